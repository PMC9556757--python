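"""Synthetic multi-region expression studies with planted ground truth.

The generator emulates a multi-region, two-sex, two-arm animal study with
animal-matched samples across brain regions: each animal contributes one
sample per region, and carries per-animal behavioral traits.  Expression
follows a latent-factor Gaussian model on the log scale,

    x_gs = lambda_g * f_m(animal(s)) + eps,   eps ~ N(0, sigma^2),

where each planted module m has an animal-level factor f_m ~ N(0, 1),
shifted by a treatment effect delta for treated animals.  Cross-region
couplings share an animal's factor between modules of two regions, which is
what makes eigengene-eigengene correlation across regions meaningful.
Traits are linear in the factors plus noise; GWAS markers live in
exchangeable-correlation LD blocks with planted low-p signal on one
module's markers; the directed network is preferential-attachment with
planted hub nodes whose out-neighborhoods cover a designated module.

Everything is deterministic under the config seed, and the returned
:class:`GroundTruth` is sufficient to score recovery of every planted
structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    DirectedGeneNetwork,
    ExpressionMatrix,
    ExpressionStudy,
    MarkerTable,
    TraitSchema,
    align_study,
)


class SimulationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass
class PlantedModule:
    """One planted coexpression module.

    ``loading`` is the within-module factor loading (lambda), ``delta`` the
    treatment shift of the module factor, and ``trait_couplings`` maps trait
    name -> beta, the linear effect of the factor on that trait.
    """

    name: str
    region: str
    size: int
    sexes: tuple[str, ...] = ("F", "M")
    loading: float = 0.9
    delta: float = 0.0
    trait_couplings: dict[str, float] = field(default_factory=dict)
    # per-gene loading heterogeneity: lambda_g = loading * U(lo, hi).
    # None means a constant loading; a range like (0.3, 1.0) creates
    # within-module hub structure and a smoother connectivity spectrum.
    loading_range: tuple[float, float] | None = None


@dataclass
class CrossRegionCoupling:
    """Share module A's animal factor with module B at the given weight."""

    module_a: str
    module_b: str
    weight: float = 0.9


@dataclass
class GwasConfig:
    n_markers: int = 2000
    block_size: int = 10
    within_block_r2: float = 0.8
    enriched_module: str | None = None
    signal_strength: float = 6.0  # p = U^(1+strength) for planted markers
    window_bp: int = 50_000


@dataclass
class NetworkConfig:
    n_nodes: int = 500
    attachment: int = 2  # out-edges gained by each existing node, on average
    hubs: dict[str, str] = field(default_factory=dict)  # hub label -> module
    hub_coverage: float = 0.9
    hub_capacity: int = 500


@dataclass
class SimulationConfig:
    """Full specification of a synthetic study; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 300
    n_animals_per_group: int = 6
    regions: tuple[str, ...] = ("PFC", "NAc", "DMS", "Amy", "VTA")
    sexes: tuple[str, ...] = ("F", "M")
    noise_sd: float = 0.3
    treatment_trait_effect: float = 0.0
    trait_noise_sd: float = 1.0
    modules: list[PlantedModule] = field(default_factory=list)
    couplings: list[CrossRegionCoupling] = field(default_factory=list)
    gwas: GwasConfig = field(default_factory=GwasConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    schema: TraitSchema = field(default_factory=TraitSchema)


@dataclass
class GroundTruth:
    """Record of everything planted, sufficient to score recovery."""

    modules: dict[str, PlantedModule]
    module_genes: dict[str, list[str]]
    factors: pd.DataFrame  # animals x modules, the true latent factors
    couplings: list[CrossRegionCoupling]
    gwas_enriched_module: str | None = None
    gwas_module_markers: list[str] = field(default_factory=list)
    hubs: dict[str, str] = field(default_factory=dict)  # hub node -> module

    def to_json(self, path) -> None:
        payload = {
            "modules": {n: asdict(m) for n, m in self.modules.items()},
            "module_genes": self.module_genes,
            "factors": self.factors.to_dict(orient="index"),
            "couplings": [asdict(c) for c in self.couplings],
            "gwas_enriched_module": self.gwas_enriched_module,
            "gwas_module_markers": self.gwas_module_markers,
            "hubs": self.hubs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _validate_modules(config: SimulationConfig) -> dict[str, list[str]]:
    """Assign disjoint gene blocks to modules; error if they overrun."""
    genes = _gene_ids(config.n_genes)
    offset = 0
    module_genes: dict[str, list[str]] = {}
    for mod in config.modules:
        if mod.size <= 0:
            raise SimulationError(f"module {mod.name!r} has non-positive size")
        if offset + mod.size > config.n_genes:
            raise SimulationError(
                f"planted module sizes exceed n_genes={config.n_genes}"
            )
        module_genes[mod.name] = genes[offset : offset + mod.size]
        offset += mod.size
    return module_genes


def _animal_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for sex in config.sexes:
        for trt in ("VEH", "THC"):
            for i in range(config.n_animals_per_group):
                rows.append(
                    {"animal_id": f"{sex}_{trt}_{i + 1:02d}", "sex": sex,
                     "treatment": trt}
                )
    return pd.DataFrame(rows)


def _draw_factors(
    config: SimulationConfig, animals: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Animal-level module factors, treatment-shifted, couplings applied."""
    names = [m.name for m in config.modules]
    if len(set(names)) != len(names):
        raise SimulationError("module names must be unique")
    factors = pd.DataFrame(
        rng.standard_normal((len(animals), len(names))),
        index=animals["animal_id"],
        columns=names,
    )
    by_name = {m.name: m for m in config.modules}
    for coup in config.couplings:
        for key in (coup.module_a, coup.module_b):
            if key not in by_name:
                raise SimulationError(f"coupling references unknown module {key!r}")
        w = coup.weight
        eta = rng.standard_normal(len(animals))
        factors[coup.module_b] = (
            w * factors[coup.module_a].to_numpy() + np.sqrt(1.0 - w**2) * eta
        )
    thc = (animals["treatment"] == "THC").to_numpy()
    for mod in config.modules:
        if mod.delta:
            col = factors.columns.get_loc(mod.name)
            factors.iloc[thc, col] += mod.delta
    return factors


def simulate_study(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate the aligned expression study and its ground truth.

    Samples are one per (animal, region); module structure is injected only
    in the module's own region and sex scope.
    """
    rng = np.random.default_rng([config.seed, 0])
    module_genes = _validate_modules(config)
    genes = _gene_ids(config.n_genes)
    animals = _animal_table(config)
    factors = _draw_factors(config, animals, rng)

    design_rows = []
    for _, a in animals.iterrows():
        for region in config.regions:
            design_rows.append(
                {
                    "sample_id": f"{a.animal_id}_{region}",
                    "animal_id": a.animal_id,
                    "sex": a.sex,
                    "region": region,
                    "treatment": a.treatment,
                }
            )
    design = pd.DataFrame(design_rows)

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(design)))
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_sex = design["sex"].to_numpy()
    sample_region = design["region"].to_numpy()
    sample_animal = design["animal_id"].to_numpy()
    for mod in config.modules:
        in_scope = (sample_region == mod.region) & np.isin(
            sample_sex, list(mod.sexes)
        )
        if not in_scope.any():
            continue
        f = factors.loc[sample_animal[in_scope], mod.name].to_numpy()
        rows = [gene_index[g] for g in module_genes[mod.name]]
        if mod.loading_range is not None:
            lo, hi = mod.loading_range
            lam = mod.loading * rng.uniform(lo, hi, size=len(rows))
        else:
            lam = np.full(len(rows), mod.loading)
        values[np.ix_(rows, in_scope.nonzero()[0])] += lam[:, None] * f

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=list(design["sample_id"]))
    )
    truth = GroundTruth(
        modules={m.name: m for m in config.modules},
        module_genes=module_genes,
        factors=factors,
        couplings=list(config.couplings),
    )
    traits = simulate_traits(config, animals, truth)
    study = align_study(expr, design, traits, config.schema)
    return study, truth


def simulate_traits(
    config: SimulationConfig, animals: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """Per-animal traits: sum of coupled module factors + treatment + noise."""
    rng = np.random.default_rng([config.seed, 1])
    thc = (animals["treatment"] == "THC").to_numpy(dtype=float)
    out = {"animal_id": animals["animal_id"].to_numpy()}
    for trait in config.schema.all_traits:
        t = config.treatment_trait_effect * thc + config.trait_noise_sd * (
            rng.standard_normal(len(animals))
        )
        for mod in config.modules:
            beta = mod.trait_couplings.get(trait, 0.0)
            if beta == 0.0:
                continue
            if mod.name not in truth.modules:
                raise SimulationError(
                    f"trait {trait!r} coupled to unknown module {mod.name!r}"
                )
            in_scope = animals["sex"].isin(mod.sexes).to_numpy(dtype=float)
            f = truth.factors.loc[animals["animal_id"], mod.name].to_numpy()
            t = t + beta * f * in_scope
        out[trait] = t
    return pd.DataFrame(out)


def simulate_gwas(
    config: SimulationConfig, gene_ids: list[str], truth: GroundTruth | None = None
):
    """Markers in LD blocks, a proximity marker->gene map, and planted signal.

    Genes are laid on one chromosome with 100 kb spacing and 20 kb spans;
    markers are spread uniformly and mapped to every gene whose span plus
    the window contains them.  Markers mapping to the enriched module's
    genes draw p = U^(1+strength); all others draw p ~ U(0, 1].

    Returns ``(MarkerTable, marker_gene_map, gene_spans, LdInfo)``.
    """
    from .gwas import LdInfo, map_markers_to_genes

    g = config.gwas
    rng = np.random.default_rng([config.seed, 2])
    if g.block_size > g.n_markers:
        raise SimulationError("LD block size exceeds number of markers")

    spacing, span = 100_000, 20_000
    gene_spans = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "1",
            "start": [i * spacing + 1 for i in range(len(gene_ids))],
            "end": [i * spacing + span for i in range(len(gene_ids))],
        }
    )
    genome = len(gene_ids) * spacing
    pos = np.sort(rng.integers(1, genome, size=g.n_markers))
    marker_ids = [f"rs{i:06d}" for i in range(g.n_markers)]
    markers = pd.DataFrame({"marker_id": marker_ids, "chrom": "1", "pos": pos})

    mapping = map_markers_to_genes(
        MarkerTable(markers.assign(p=0.5)), gene_spans, window_bp=g.window_bp
    )
    enriched_genes: set[str] = set()
    if g.enriched_module is not None:
        if truth is None or g.enriched_module not in truth.module_genes:
            raise SimulationError(
                f"enriched module {g.enriched_module!r} not in ground truth"
            )
        enriched_genes = set(truth.module_genes[g.enriched_module])

    u = rng.uniform(0.0, 1.0, size=g.n_markers)
    p = np.clip(u, 1e-300, 1.0)
    module_markers = []
    for i, mid in enumerate(marker_ids):
        if enriched_genes and set(mapping.get(mid, ())) & enriched_genes:
            p[i] = max(u[i] ** (1.0 + g.signal_strength), 1e-300)
            module_markers.append(mid)
    table = MarkerTable(markers.assign(p=p))

    blocks = {mid: i // g.block_size for i, mid in enumerate(marker_ids)}
    ld = LdInfo(blocks=blocks, within_r2=g.within_block_r2)
    if truth is not None:
        truth.gwas_enriched_module = g.enriched_module
        truth.gwas_module_markers = module_markers
    return table, mapping, gene_spans, ld


def simulate_network(
    config: SimulationConfig, truth: GroundTruth
) -> DirectedGeneNetwork:
    """Scale-free-ish directed graph with planted hub -> module structure.

    Preferential attachment: nodes are added in order and each new node
    receives ``attachment`` in-edges from existing nodes chosen with
    probability proportional to out-degree + 1, so early/lucky nodes grow
    heavy out-neighborhoods (regulator -> target semantics).  Each planted
    hub then gains direct out-edges to ``hub_coverage`` of its module.
    """
    net = config.network
    rng = np.random.default_rng([config.seed, 3])
    genes = _gene_ids(config.n_genes)
    n_nodes = min(net.n_nodes, len(genes))
    # insertion order is shuffled so planted-module genes are not the early
    # (high out-degree) core of the attachment process
    nodes = [genes[i] for i in rng.permutation(n_nodes)]

    edges: list[tuple[str, str]] = []
    out_deg = np.zeros(n_nodes)
    for i in range(1, n_nodes):
        k = min(net.attachment, i)
        w = out_deg[:i] + 1.0
        srcs = rng.choice(i, size=k, replace=False, p=w / w.sum())
        for s in srcs:
            edges.append((nodes[s], nodes[i]))
            out_deg[s] += 1

    hubs: dict[str, str] = {}
    module_nodes = {
        g for m in net.hubs.values() for g in truth.module_genes.get(m, [])
    }
    background = [g for g in nodes if g not in module_nodes]
    for hub_label, module in net.hubs.items():
        if module not in truth.module_genes:
            raise SimulationError(f"hub {hub_label!r} references unknown module")
        members = [g for g in truth.module_genes[module] if g in set(nodes)]
        n_cover = int(np.ceil(net.hub_coverage * len(members)))
        if n_cover > net.hub_capacity:
            raise SimulationError(
                f"module {module!r} ({n_cover} genes to cover) exceeds hub "
                f"capacity {net.hub_capacity}"
            )
        if not background:
            raise SimulationError("no background node available to host a hub")
        hub = background.pop(int(rng.integers(len(background))))
        chosen = rng.choice(len(members), size=n_cover, replace=False)
        for j in sorted(chosen):
            edges.append((hub, members[j]))
        hubs[hub] = module

    truth.hubs = hubs
    network = DirectedGeneNetwork.from_edges(edges)
    # isolated nodes still count toward the universe
    network.graph.add_nodes_from(nodes)
    return network


def nb_counts(
    expr: ExpressionMatrix, dispersion: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Optional count layer: NB draws with mean exp(x), fixed dispersion."""
    rng = np.random.default_rng(seed)
    mu = np.exp(expr.values)
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=expr.gene_ids, columns=expr.sample_ids)
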