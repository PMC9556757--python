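"""Threshold-free rank-rank hypergeometric overlap of two DE signatures.

Each gene carries a signed score, -log10(p) * sign(logFC).  The stratified
construction splits each signature by score sign before ranking, yielding
four quadrants (up/up, down/down, up/down, down/up).  Within a quadrant,
both lists are ranked by decreasing |score| and, at each grid point, the
overlap of the two top-sets is scored by a hypergeometric tail over the
common-gene universe; cells are signed: positive for over-representation
(-log10 P(X >= k)), negative for depletion (+log10 P(X <= k) flipped).
Concordant signatures light up up/up and down/down; sign-flipped
(opposing) signatures light up the discordant quadrants instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RrhoMap:
    step: int
    quadrants: dict[str, np.ndarray]  # keys: uu, dd, ud, du
    n_common: int
    meta: dict


def make_signature(
    table: pd.DataFrame, p_floor: float = 1e-300
) -> pd.Series:
    """Signed score per gene: -log10(p) * sign(logFC), p floored at p_floor."""
    if not {"gene_id", "p", "logFC"} <= set(table.columns):
        raise ValueError("signature table needs gene_id, p, logFC columns")
    p = table["p"].to_numpy(dtype=float)
    if (p <= 0).any():
        warnings.warn("p-values at or below 0 floored", stacklevel=2)
    p = np.clip(p, p_floor, 1.0)
    score = -np.log10(p) * np.sign(table["logFC"].to_numpy(dtype=float))
    sig = pd.Series(score, index=table["gene_id"].to_numpy())
    if sig.index.has_duplicates:
        raise ValueError("duplicate gene ids in signature")
    return sig


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for hypergeometric(N, K, n), log-space stable."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _lower_tail(k: int, K: int, n: int, N: int) -> float:
    return float(stats.hypergeom.cdf(k, N, K, n))


def _quadrant(
    genes_a: list[str], genes_b: list[str], n_common: int, step: int
) -> np.ndarray:
    """Signed -log10 p grid over top-set sizes i*step x j*step."""
    ni = max(1, int(np.ceil(len(genes_a) / step))) if genes_a else 0
    nj = max(1, int(np.ceil(len(genes_b) / step))) if genes_b else 0
    out = np.zeros((ni, nj))
    set_b_sorted = genes_b
    b_rank = {g: r for r, g in enumerate(set_b_sorted)}
    for i in range(ni):
        top_a = genes_a[: min((i + 1) * step, len(genes_a))]
        ranks = sorted(b_rank[g] for g in top_a if g in b_rank)
        for j in range(nj):
            nb = min((j + 1) * step, len(genes_b))
            # overlap = members of top_a whose rank in B is below nb
            k = int(np.searchsorted(ranks, nb))
            K, n = len(top_a), nb
            expected = K * n / n_common
            if k >= expected:
                p = hypergeom_tail(k, K, n, n_common)
                out[i, j] = -np.log10(max(p, 1e-300))
            else:
                p = _lower_tail(k, K, n, n_common)
                out[i, j] = np.log10(max(p, 1e-300))
    return out


def rrho_map(
    sig_a: pd.Series, sig_b: pd.Series, step: int | None = None
) -> RrhoMap:
    """Stratified four-quadrant overlap map of two signed signatures."""
    common = sig_a.index.intersection(sig_b.index)
    # deterministic ordering: |score| descending, gene id as tie-break
    n_common = len(common)
    if step is None:
        step = max(1, n_common // 100)
    if n_common < 2 * step:
        raise ValueError(
            f"need >= {2 * step} common genes, got {n_common}"
        )
    a = sig_a.loc[common]
    b = sig_b.loc[common]

    def ranked(sig: pd.Series, positive: bool) -> list[str]:
        sel = sig[sig > 0] if positive else sig[sig < 0]
        order = sorted(sel.index, key=lambda g: (-abs(sel[g]), g))
        return order

    a_up, a_dn = ranked(a, True), ranked(a, False)
    b_up, b_dn = ranked(b, True), ranked(b, False)
    quadrants = {
        "uu": _quadrant(a_up, b_up, n_common, step),
        "dd": _quadrant(a_dn, b_dn, n_common, step),
        "ud": _quadrant(a_up, b_dn, n_common, step),
        "du": _quadrant(a_dn, b_up, n_common, step),
    }
    return RrhoMap(
        step=step,
        quadrants=quadrants,
        n_common=n_common,
        meta={
            "n_up_a": len(a_up),
            "n_down_a": len(a_dn),
            "n_up_b": len(b_up),
            "n_down_b": len(b_dn),
        },
    )


def write_rrho_map(rmap: RrhoMap, prefix: str) -> None:
    """Export the four quadrant matrices as TSV plus JSON metadata."""
    import json

    for name, mat in rmap.quadrants.items():
        pd.DataFrame(mat).to_csv(f"{prefix}.{name}.tsv", sep="\t", index=False)
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(
            {"step": rmap.step, "n_common": rmap.n_common, **rmap.meta}, fh, indent=1
        )
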