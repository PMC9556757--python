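"""Domain types and file I/O shared by every analysis stage.

The central container is :class:`ExpressionStudy`, which aligns a log-scale
expression matrix (genes x samples) with the sample design (animal, sex,
brain region, treatment) and per-animal behavioral traits.  All tabular
formats are plain tab-delimited text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

SEXES = ("F", "M")
TREATMENTS = ("VEH", "THC")
DEFAULT_REGIONS = ("PFC", "NAc", "DMS", "Amy", "VTA")

DESIGN_COLUMNS = ["sample_id", "animal_id", "sex", "region", "treatment"]


class DataModelError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


@dataclass
class TraitSchema:
    """Declares which traits count as memory traits vs social traits.

    The default mirrors a recognition-memory battery: absolute (D1) and
    relative (D2) object-discrimination indexes, novel-object exploration
    time (seconds), and social preference (percent).
    """

    memory_traits: tuple[str, ...] = ("D1", "D2", "novel_exploration")
    social_traits: tuple[str, ...] = ("social_preference",)

    @property
    def all_traits(self) -> tuple[str, ...]:
        return tuple(self.memory_traits) + tuple(self.social_traits)


@dataclass
class ExpressionMatrix:
    """Log-scale normalized expression, genes in rows, samples in columns."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataModelError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataModelError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float, copy=False)).all():
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise DataModelError(
                f"non-finite expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Raises :class:`DataModelError` naming the offending cell on blank or
    non-numeric entries, and the offending id on duplicates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            cell = raw[col].iloc[i]
            what = "blank" if cell == "" else f"non-numeric ({cell!r})"
            raise DataModelError(
                f"{what} cell at row {raw.index[i]!r} (line {i + 2}), "
                f"column {col!r} (column {j + 2})"
            )
        raw[col] = converted
    return ExpressionMatrix(raw.astype(float))


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    return validate_design(design)


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DataModelError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataModelError(f"duplicate sample id in design: {dup!r}")
    bad_sex = set(design["sex"]) - set(SEXES)
    if bad_sex:
        raise DataModelError(f"unknown sex codes: {sorted(bad_sex)} (expected {SEXES})")
    bad_trt = set(design["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise DataModelError(
            f"unknown treatment codes: {sorted(bad_trt)} (expected {TREATMENTS})"
        )
    pair = design[["animal_id", "region"]]
    if pair.duplicated().any():
        a, r = pair.loc[pair.duplicated()].iloc[0]
        raise DataModelError(f"animal {a!r} has multiple samples in region {r!r}")
    for col in ("sex", "treatment"):
        per_animal = design.groupby("animal_id")[col].nunique()
        if (per_animal > 1).any():
            a = per_animal[per_animal > 1].index[0]
            raise DataModelError(f"animal {a!r} has inconsistent {col} across samples")
    return design.reset_index(drop=True)


def read_trait_tsv(path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t")
    return validate_traits(traits)


def write_trait_tsv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index=False)


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    if "animal_id" not in traits.columns:
        raise DataModelError("trait table must have an 'animal_id' column")
    if traits["animal_id"].duplicated().any():
        dup = traits.loc[traits["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise DataModelError(f"duplicate animal id in trait table: {dup!r}")
    traits = traits.copy()
    traits["animal_id"] = traits["animal_id"].astype(str)
    return traits.reset_index(drop=True)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, cell-type markers) with descriptions."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise DataModelError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read standard GMT: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise DataModelError(f"GMT line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise DataModelError(f"GMT line {lineno}: duplicate set name {name!r}")
            # dedup preserving order: enrichment must not depend on repeats
            seen: dict[str, None] = dict.fromkeys(genes)
            sets[name] = (desc, list(seen))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class MarkerTable:
    """GWAS summary statistics: marker id, chromosome, position (bp), p."""

    data: pd.DataFrame  # columns: marker_id, chrom, pos, p

    def __post_init__(self) -> None:
        required = ["marker_id", "chrom", "pos", "p"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise DataModelError(f"marker table missing columns: {missing}")
        if self.data["marker_id"].duplicated().any():
            dup = self.data.loc[self.data["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise DataModelError(f"duplicate marker id: {dup!r}")
        p = self.data["p"].to_numpy(dtype=float)
        if ((p <= 0) | (p > 1)).any():
            bad = self.data["marker_id"].iloc[int(np.argmax((p <= 0) | (p > 1)))]
            raise DataModelError(f"marker {bad!r} has p outside (0, 1]")

    def __len__(self) -> int:
        return len(self.data)


def read_marker_tsv(path) -> MarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    df["pos"] = df["pos"].astype(int)
    df["p"] = df["p"].astype(float)
    return MarkerTable(df)


def write_marker_tsv(markers: MarkerTable, path) -> None:
    markers.data.to_csv(path, sep="\t", index=False)


@dataclass
class DirectedGeneNetwork:
    """Directed gene-gene network (regulator -> target edge semantics)."""

    graph: nx.DiGraph

    @classmethod
    def from_edges(cls, edges) -> "DirectedGeneNetwork":
        g = nx.DiGraph()
        for src, dst in edges:
            if src == dst:
                continue  # self-loops dropped on load
            g.add_edge(str(src), str(dst))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def read_network_tsv(path) -> DirectedGeneNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataModelError("network edge list needs two columns (source, target)")
    return DirectedGeneNetwork.from_edges(df.iloc[:, :2].itertuples(index=False))


def write_network_tsv(network: DirectedGeneNetwork, path) -> None:
    pd.DataFrame(network.edges, columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class ExpressionStudy:
    """Expression + design + traits, aligned on samples and animals."""

    expr: ExpressionMatrix
    design: pd.DataFrame
    traits: pd.DataFrame
    schema: TraitSchema = field(default_factory=TraitSchema)

    @property
    def sample_ids(self) -> list[str]:
        return self.expr.sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.expr.gene_ids

    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.design["animal_id"]))

    def treatment_indicator(self) -> np.ndarray:
        """0/1 vector over samples: VEH=0, THC=1."""
        return (self.design["treatment"] == "THC").to_numpy(dtype=float)


def align_study(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    traits: pd.DataFrame,
    schema: TraitSchema | None = None,
) -> ExpressionStudy:
    """Align samples to the design order and join traits by animal id.

    Expression samples absent from the design are a hard error; animals
    without a trait row raise a warning and are carried with NaN traits.
    """
    design = validate_design(design)
    traits = validate_traits(traits)
    missing = [s for s in expr.sample_ids if s not in set(design["sample_id"])]
    if missing:
        raise DataModelError(f"expression sample missing from design: {missing[0]!r}")
    # deterministic order: design order, restricted to samples with expression
    keep = design["sample_id"].isin(set(expr.sample_ids))
    design = design.loc[keep].reset_index(drop=True)
    expr = ExpressionMatrix(expr.data.loc[:, list(design["sample_id"])])
    lacking = sorted(set(design["animal_id"]) - set(traits["animal_id"]))
    if lacking:
        warnings.warn(
            f"{len(lacking)} animal(s) lack trait rows: {lacking}", stacklevel=2
        )
    return ExpressionStudy(expr, design, traits, schema or TraitSchema())


def subset_by(study: ExpressionStudy, region: str, sex: str) -> ExpressionStudy:
    """Restrict a study to one (region, sex) stratum; gene set unchanged."""
    mask = (study.design["region"] == region) & (study.design["sex"] == sex)
    if not mask.any():
        raise DataModelError(f"no samples for region={region!r}, sex={sex!r}")
    design = study.design.loc[mask].reset_index(drop=True)
    expr = ExpressionMatrix(study.expr.data.loc[:, list(design["sample_id"])])
    return ExpressionStudy(expr, design, study.traits, study.schema)


def log2_cpm(counts: pd.DataFrame, pseudo: float = 0.5) -> pd.DataFrame:
    """log2(counts-per-million + pseudo) normalization of an integer matrix."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise DataModelError("library size must be positive for every sample")
    cpm = counts.astype(float) / lib * 1e6
    return np.log2(cpm + pseudo)
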