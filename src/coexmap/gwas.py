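"""GWAS-to-network integration: LD pruning, gene mapping, MSEA.

The workflow follows the marker-set enrichment idea: prune markers in
linkage disequilibrium keeping the most significant representative (marker
dependency filtering), map markers to genes by proximity, then test whether
a module's markers are shifted toward low GWAS p-values.  The statistic
aggregates observed vs expected marker counts over several top-p quantile
cutoffs,

    Q = sum_i (O_i - E_i) / sqrt(E_i + kappa),

with O_i the module markers below the i-th quantile of all pruned marker
p-values, E_i the count expected under uniformity, and kappa a variance
stabilizer (default 1).  Significance comes from size-matched random gene
sets drawn from the mapped universe (gene-label permutation, which respects
per-gene marker multiplicity), with add-one smoothing; modules are called
associated at BH FDR < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MarkerTable
from .diffexpr import bh_fdr

DEFAULT_CUTOFFS = (0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class LdInfo:
    """Exchangeable-correlation LD blocks: constant r^2 within, 0 between."""

    blocks: dict[str, int]
    within_r2: float

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self.blocks.get(a) is not None and self.blocks.get(a) == self.blocks.get(b):
            return self.within_r2
        return 0.0


def marker_dependency_filter(
    markers: MarkerTable, ld: LdInfo, r2_max: float = 0.5
) -> MarkerTable:
    """Greedy LD pruning: keep the lowest-p marker, drop its LD partners.

    Ties on p break lexicographically by marker id, making the output
    independent of input order.
    """
    df = markers.data.sort_values(["p", "marker_id"], kind="stable")
    kept: list[str] = []
    removed: set[str] = set()
    # group remaining markers by block for O(n) partner lookup
    by_block: dict[int | None, list[str]] = {}
    for mid in df["marker_id"]:
        by_block.setdefault(ld.blocks.get(mid), []).append(mid)
    for mid in df["marker_id"]:
        if mid in removed:
            continue
        kept.append(mid)
        block = ld.blocks.get(mid)
        if block is not None and ld.within_r2 > r2_max:
            for other in by_block.get(block, ()):
                if other != mid:
                    removed.add(other)
    keep_set = set(kept)
    out = markers.data[markers.data["marker_id"].isin(keep_set)].reset_index(
        drop=True
    )
    return MarkerTable(out)


def map_markers_to_genes(
    markers: MarkerTable, gene_spans: pd.DataFrame, window_bp: int = 50_000
) -> dict[str, list[str]]:
    """Map each marker to genes whose span +/- window contains its position.

    ``gene_spans`` needs columns gene_id, chrom, start, end.  Unmapped
    markers are retained with an empty list; multi-mapping is allowed.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    required = {"gene_id", "chrom", "start", "end"}
    if not required <= set(gene_spans.columns):
        raise ValueError(f"gene_spans needs columns {sorted(required)}")
    mapping: dict[str, list[str]] = {}
    by_chrom = {
        str(c): g.sort_values("start") for c, g in gene_spans.groupby("chrom")
    }
    for row in markers.data.itertuples():
        genes: list[str] = []
        spans = by_chrom.get(str(row.chrom))
        if spans is not None:
            lo = spans["start"].to_numpy() - window_bp
            hi = spans["end"].to_numpy() + window_bp
            hit = (row.pos >= lo) & (row.pos <= hi)
            genes = list(spans["gene_id"].to_numpy()[hit])
        mapping[row.marker_id] = genes
    return mapping


def select_significant_loci(
    markers: MarkerTable, p_max: float = 0.001
) -> MarkerTable:
    """Strict p < p_max locus filter (a marker at exactly p_max is dropped)."""
    out = markers.data[markers.data["p"] < p_max].reset_index(drop=True)
    if out.empty:
        warnings.warn(
            f"no markers pass p < {p_max}; association labels will be empty",
            stacklevel=2,
        )
    return MarkerTable(out)


def associated_genes(
    markers: MarkerTable,
    mapping: dict[str, list[str]],
    p_max: float = 0.001,
) -> set[str]:
    """Genes tagged by at least one marker passing the locus filter."""
    loci = select_significant_loci(markers, p_max)
    out: set[str] = set()
    for mid in loci.data["marker_id"]:
        out.update(mapping.get(mid, ()))
    return out


def _gene_to_markers(
    mapping: dict[str, list[str]], pruned_ids: set[str]
) -> dict[str, list[str]]:
    g2m: dict[str, list[str]] = {}
    for mid, genes in mapping.items():
        if mid not in pruned_ids:
            continue
        for g in genes:
            g2m.setdefault(g, []).append(mid)
    return g2m


def _q_statistic(
    marker_ids, p_by_marker: dict[str, float], thresholds, cutoffs, kappa: float
) -> float:
    ps = np.array([p_by_marker[m] for m in set(marker_ids)])
    if ps.size == 0:
        return np.nan
    q = 0.0
    for thr, frac in zip(thresholds, cutoffs):
        o = float((ps <= thr).sum())
        e = ps.size * frac
        q += (o - e) / np.sqrt(e + kappa)
    return q


def msea(
    module_genes,
    mapping: dict[str, list[str]],
    pruned: MarkerTable,
    cutoffs=DEFAULT_CUTOFFS,
    kappa: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Marker-set enrichment of one module; returns stats + permutation p."""
    pruned_ids = set(pruned.data["marker_id"])
    p_by_marker = dict(zip(pruned.data["marker_id"], pruned.data["p"]))
    g2m = _gene_to_markers(mapping, pruned_ids)
    module_genes = [g for g in module_genes if g in g2m]
    module_markers = sorted({m for g in module_genes for m in g2m[g]})
    if not module_markers:
        warnings.warn("module has no mapped markers; MSEA reported as NA",
                      stacklevel=2)
        return {
            "n_genes": 0, "n_markers": 0, "Q": np.nan, "p": np.nan,
            "observed": [], "expected": [],
        }
    all_p = pruned.data["p"].to_numpy(dtype=float)
    thresholds = [float(np.quantile(all_p, c)) for c in cutoffs]
    q_obs = _q_statistic(module_markers, p_by_marker, thresholds, cutoffs, kappa)
    ps = np.array([p_by_marker[m] for m in module_markers])
    observed = [int((ps <= t).sum()) for t in thresholds]
    expected = [len(module_markers) * c for c in cutoffs]

    rng = np.random.default_rng(seed)
    universe = sorted(g2m)
    size = len(module_genes)
    exceed = 0
    for _ in range(n_perm):
        draw = rng.choice(len(universe), size=size, replace=False)
        perm_markers = {m for i in draw for m in g2m[universe[i]]}
        q_null = _q_statistic(perm_markers, p_by_marker, thresholds, cutoffs, kappa)
        if q_null >= q_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return {
        "n_genes": size,
        "n_markers": len(module_markers),
        "Q": q_obs,
        "p": p,
        "observed": observed,
        "expected": expected,
    }


def msea_all(
    modules: dict[str, list[str]],
    mapping: dict[str, list[str]],
    pruned: MarkerTable,
    cutoffs=DEFAULT_CUTOFFS,
    kappa: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """MSEA across modules with BH FDR and the associated call."""
    rows = []
    for i, (name, genes) in enumerate(sorted(modules.items())):
        res = msea(
            genes, mapping, pruned, cutoffs=cutoffs, kappa=kappa,
            n_perm=n_perm, seed=seed + i,
        )
        rows.append({"module": name, **{k: res[k] for k in
                                        ("n_genes", "n_markers", "Q", "p")}})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["associated"] = out["fdr"] < alpha
    return out


def overlap_fraction(cud_modules, reference_modules) -> float:
    """Percent of associated modules that appear in the reference set."""
    cud = set(cud_modules)
    if not cud:
        warnings.warn("empty associated-module set; overlap undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * len(cud & set(reference_modules)) / len(cud)
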