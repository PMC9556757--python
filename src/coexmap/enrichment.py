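"""Over-representation tests against pathway and cell-type marker sets.

One-sided hypergeometric tail per set, BH-adjusted across the queried
collection.  The universe defaults to the genes that survived expression
filtering in the analyzed dataset (the conservative, standard background),
never the whole genome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coexpression import GREY, ModulePartition
from .datamodel import GeneSetCollection
from .diffexpr import bh_fdr
from .rrho import hypergeom_tail


def enrich(
    query,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``query`` must be a subset of ``universe``; sets are intersected with
    the universe and deduplicated so gene order and repeats cannot change
    the result.  Returns rows sorted by p then set name.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)[:3]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    N, n = len(universe), len(query)
    rows = []
    for name in sets.names():
        members = set(sets.genes(name)) & universe
        K = len(members)
        k = len(members & query)
        if K == 0:
            rows.append(
                {"set": name, "k": 0, "K": 0, "n": n, "N": N,
                 "odds_ratio": np.nan, "p": np.nan}
            )
            continue
        p = hypergeom_tail(k, K, n, N)
        # Haldane-corrected odds ratio of the 2x2 overlap table
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {"set": name, "k": k, "K": K, "n": n, "N": N,
             "odds_ratio": orr, "p": p}
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out.sort_values(["p", "set"], na_position="last").reset_index(drop=True)


def celltype_enrichment(
    partition: ModulePartition,
    marker_sets: GeneSetCollection,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Per-module marker-set enrichment; universe = all clustered genes."""
    if len(marker_sets) == 0:
        raise ValueError("marker set collection is empty")
    universe = set(partition.assignment)
    covered = set().union(*(set(marker_sets.genes(s)) for s in marker_sets.names()))
    if not covered & universe:
        warnings.warn(
            "marker sets share no genes with the clustered universe; "
            "results will be NA",
            stacklevel=2,
        )
    frames = []
    for module in partition.labels:
        if module == GREY and not include_grey:
            continue
        res = enrich(partition.members(module), marker_sets, universe)
        res.insert(0, "module", module)
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
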