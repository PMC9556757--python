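"""Module-trait correlation, module taxonomy, cross-region module map.

A module is *treatment-correlated* when its eigengene correlates with the
treatment indicator at p < alpha (point-biserial, uncorrected, matching the
convention of reporting nominally significant module-trait correlations);
*cognitive* when additionally correlated with at least one memory trait;
and *interconnected* when it has at least one qualifying edge
(|r| > 0.5 and p < 0.05 by default) to a treatment-correlated module within
or across brain regions.  Cross-region correlations are computed over the
animals shared by the two regions (animal-matched sampling makes this
meaningful), pooling both treatment arms within one sex by default, with an
optional treatment-residualized sensitivity mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import GREY, EigengeneMatrix
from .datamodel import ExpressionStudy, TraitSchema


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with t-based p, pairwise-dropping missing values."""
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 4:
        return np.nan, np.nan, n
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


@dataclass
class ModuleTraitProfile:
    """Long-form (module, variable) correlation table with taxonomy flags."""

    table: pd.DataFrame  # region, sex, module, variable, r, p, n
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)
    # flags columns: region, sex, module, thc_correlated, cognitive,
    # social_correlated, memory_correlated


def module_trait_correlation(
    eigengenes: EigengeneMatrix,
    study: ExpressionStudy,
    region: str = "",
    sex: str = "",
) -> ModuleTraitProfile:
    """Correlate each eigengene with treatment and every trait."""
    design = study.design.set_index("sample_id").loc[eigengenes.sample_ids]
    trt = (design["treatment"] == "THC").to_numpy(dtype=float)
    traits = study.traits.set_index("animal_id")
    animal_ids = design["animal_id"].to_numpy()
    rows = []
    for module in eigengenes.modules:
        e = eigengenes.data.loc[module].to_numpy(dtype=float)
        variables = {"treatment": trt}
        for trait in study.schema.all_traits:
            if trait in traits.columns:
                variables[trait] = np.array(
                    [
                        traits.at[a, trait] if a in traits.index else np.nan
                        for a in animal_ids
                    ],
                    dtype=float,
                )
        for var, y in variables.items():
            r, p, n = correlation_with_p(e, y)
            if np.isnan(r) and n >= 4:
                warnings.warn(
                    f"zero-variance variable {var!r} for module {module!r}",
                    stacklevel=2,
                )
            elif n < 4:
                warnings.warn(
                    f"fewer than 4 paired observations for module {module!r} "
                    f"x {var!r}; reporting NA",
                    stacklevel=2,
                )
            rows.append(
                {
                    "region": region,
                    "sex": sex,
                    "module": module,
                    "variable": var,
                    "r": r,
                    "p": p,
                    "n": n,
                }
            )
    return ModuleTraitProfile(
        pd.DataFrame(
            rows,
            columns=["region", "sex", "module", "variable", "r", "p", "n"],
        )
    )


def classify_modules(
    profile: ModuleTraitProfile,
    schema: TraitSchema | None = None,
    alpha: float = 0.05,
) -> ModuleTraitProfile:
    """Apply the taxonomy: treatment-correlated / cognitive / social flags."""
    schema = schema or TraitSchema()
    table = profile.table
    flag_cols = ["region", "sex", "module", "thc_correlated",
                 "memory_correlated", "cognitive", "social_correlated"]
    if table.empty:
        return ModuleTraitProfile(table, pd.DataFrame(columns=flag_cols))
    known = set(table["variable"])
    for trait in schema.memory_traits:
        if trait not in known:
            raise ValueError(f"memory trait {trait!r} not in profile variables")
    flags = []
    for (region, sex, module), grp in table.groupby(
        ["region", "sex", "module"], sort=False
    ):
        by_var = grp.set_index("variable")
        p_trt = by_var.at["treatment", "p"] if "treatment" in by_var.index else np.nan
        thc = bool(p_trt < alpha) if np.isfinite(p_trt) else False
        memory = any(
            np.isfinite(by_var.at[t, "p"]) and by_var.at[t, "p"] < alpha
            for t in schema.memory_traits
            if t in by_var.index
        )
        social = any(
            np.isfinite(by_var.at[t, "p"]) and by_var.at[t, "p"] < alpha
            for t in schema.social_traits
            if t in by_var.index
        )
        flags.append(
            {
                "region": region,
                "sex": sex,
                "module": module,
                "thc_correlated": thc,
                "memory_correlated": memory,
                "cognitive": thc and memory,
                "social_correlated": social,
            }
        )
    return ModuleTraitProfile(table, pd.DataFrame(flags, columns=flag_cols))


def _residualize(e: np.ndarray, trt: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(trt), trt])
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    return e - X @ beta


def cross_module_correlation(
    eigengene_sets: dict[str, EigengeneMatrix],
    study: ExpressionStudy,
    sex: str,
    partial_treatment: bool = False,
) -> pd.DataFrame:
    """All unordered module-pair correlations within and between regions.

    ``eigengene_sets`` maps region -> eigengenes for that region's samples
    of the given sex.  Eigengenes are joined on animal id; a pair needs at
    least 4 shared animals.  Same-region pairs of distinct modules are
    included; grey is excluded.
    """
    design = study.design.set_index("sample_id")
    per_region: dict[str, pd.DataFrame] = {}
    trt_by_animal = (
        study.design.drop_duplicates("animal_id")
        .set_index("animal_id")["treatment"]
        .eq("THC")
        .astype(float)
    )
    for region, eigs in eigengene_sets.items():
        animals = design.loc[eigs.sample_ids, "animal_id"].to_numpy()
        df = pd.DataFrame(
            eigs.data.to_numpy().T, index=animals, columns=eigs.modules
        )
        per_region[region] = df.drop(columns=[GREY], errors="ignore")

    items = [
        (region, module)
        for region in sorted(per_region)
        for module in per_region[region].columns
    ]
    rows = []
    for idx_a in range(len(items)):
        for idx_b in range(idx_a + 1, len(items)):
            ra, ma = items[idx_a]
            rb, mb = items[idx_b]
            a = per_region[ra][ma]
            b = per_region[rb][mb]
            shared = a.index.intersection(b.index)
            if len(shared) < 4:
                warnings.warn(
                    f"pair ({ra},{ma}) x ({rb},{mb}): <4 shared animals, skipped",
                    stacklevel=2,
                )
                continue
            xa = a.loc[shared].to_numpy(dtype=float)
            xb = b.loc[shared].to_numpy(dtype=float)
            if partial_treatment:
                trt = trt_by_animal.loc[shared].to_numpy()
                xa, xb = _residualize(xa, trt), _residualize(xb, trt)
            r, p, n = correlation_with_p(xa, xb)
            rows.append(
                {
                    "region_a": ra, "module_a": ma,
                    "region_b": rb, "module_b": mb,
                    "r": r, "p": p, "n": n,
                    "sign": "pos" if r >= 0 else "neg",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region_a", "module_a", "region_b", "module_b", "r", "p", "n",
                 "sign"],
    )


def qualifying_edges(
    edges: pd.DataFrame, r_min: float = 0.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Edges with |r| strictly above r_min and p strictly below alpha."""
    if edges.empty:
        return edges
    mask = (edges["r"].abs() > r_min) & (edges["p"] < alpha)
    return edges.loc[mask].reset_index(drop=True)


def interconnected_modules(
    edges: pd.DataFrame,
    flags: pd.DataFrame,
    r_min: float = 0.5,
    alpha: float = 0.05,
) -> set[tuple[str, str]]:
    """(region, module) pairs with a qualifying edge to a treatment-correlated
    module; a module's own treatment-correlated status is irrelevant."""
    thc = {
        (row.region, row.module)
        for row in flags.itertuples()
        if row.thc_correlated
    }
    out: set[tuple[str, str]] = set()
    for row in qualifying_edges(edges, r_min, alpha).itertuples():
        a = (row.region_a, row.module_a)
        b = (row.region_b, row.module_b)
        if b in thc:
            out.add(a)
        if a in thc:
            out.add(b)
    return out


def connectivity_tally(edges: pd.DataFrame) -> pd.DataFrame:
    """Counts of positive/negative qualifying edges per region pair."""
    if edges.empty:
        return pd.DataFrame(columns=["region_a", "region_b", "n_pos", "n_neg"])
    rows: dict[tuple[str, str], list[int]] = {}
    for row in edges.itertuples():
        key = tuple(sorted((row.region_a, row.region_b)))
        rows.setdefault(key, [0, 0])
        rows[key][0 if row.sign == "pos" else 1] += 1
    return pd.DataFrame(
        [
            {"region_a": a, "region_b": b, "n_pos": npos, "n_neg": nneg}
            for (a, b), (npos, nneg) in sorted(rows.items())
        ]
    )


def sankey_export(tally: pd.DataFrame, path) -> None:
    """Sankey-ready JSON: nodes are regions, links carry signed edge counts."""
    regions = sorted(set(tally["region_a"]) | set(tally["region_b"]))
    index = {r: i for i, r in enumerate(regions)}
    links = []
    for row in tally.itertuples():
        for sign, count in (("pos", row.n_pos), ("neg", row.n_neg)):
            if count:
                links.append(
                    {
                        "source": index[row.region_a],
                        "target": index[row.region_b],
                        "value": int(count),
                        "sign": sign,
                    }
                )
    with open(path, "w") as fh:
        json.dump({"nodes": [{"name": r} for r in regions], "links": links}, fh,
                  indent=1)
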