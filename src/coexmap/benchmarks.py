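"""Planted-truth benchmark routines.

Each function generates synthetic studies with known ground truth, runs the
relevant analysis stage, and scores recovery or calibration.  They are used
both by the test suite and by the acceptance script, and every one is
deterministic given its seed.

Problem sizes are kept small (tens of genes per module, 12-24 samples,
hundreds of markers) so a full benchmark sweep runs in minutes on one CPU;
they match the emulated study design (6 animals per treatment arm per sex)
unless a check's stated conditions say otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import coexpression as cx
from . import diffexpr, gwas, keydrivers, module_analysis
from .datamodel import subset_by
from .simulate import (
    CrossRegionCoupling,
    GwasConfig,
    NetworkConfig,
    PlantedModule,
    SimulationConfig,
    simulate_gwas,
    simulate_network,
    simulate_study,
)


def _offset(seed: int, salt: int) -> int:
    return (int(seed) * 1_000_003 + salt) % (2**31)


def module_recovery_grid(
    seed: int = 0,
    loadings=(0.7, 0.8, 0.9),
    noise_sds=(0.2, 0.3, 0.4),
    n_seeds: int = 5,
) -> list[float]:
    """ARI of detected vs planted modules over a (loading, noise) grid.

    Three 50-gene modules in 200 genes, 24 animal-matched samples.
    Returns one ARI per run (len = grid x n_seeds).
    """
    aris = []
    for lam in loadings:
        for sigma in noise_sds:
            for rep in range(n_seeds):
                config = SimulationConfig(
                    seed=_offset(seed, rep * 97 + int(lam * 100) + int(sigma * 10)),
                    n_genes=200,
                    n_animals_per_group=12,
                    regions=("A",),
                    sexes=("F",),
                    noise_sd=sigma,
                    modules=[
                        PlantedModule(f"m{i}", "A", 50, ("F",), lam, 0.0)
                        for i in range(3)
                    ],
                )
                study, truth = simulate_study(config)
                sub = subset_by(study, "A", "F")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    partition, _, tom, _ = cx.detect_modules(sub.expr)
                genes = list(tom.index)
                true_labels = [
                    next(
                        (m for m, gl in truth.module_genes.items() if g in gl),
                        "bg",
                    )
                    for g in genes
                ]
                predicted = [partition.assignment[g] for g in genes]
                aris.append(adjusted_rand_score(true_labels, predicted))
    return aris


def _true_partition(sub, truth):
    return cx.ModulePartition(
        {
            g: next(
                (m for m, gl in truth.module_genes.items() if g in gl),
                cx.GREY,
            )
            for g in sub.gene_ids
        }
    )


def _flags_for(config: SimulationConfig, region="A", sex="F"):
    study, truth = simulate_study(config)
    sub = subset_by(study, region, sex)
    eigs = cx.module_eigengene(sub.expr, _true_partition(sub, truth))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = module_analysis.module_trait_correlation(eigs, sub, region, sex)
        profile = module_analysis.classify_modules(profile, study.schema)
    return profile.flags


def null_thc_flag_rate(seed: int = 0, n_seeds: int = 100) -> tuple[int, int]:
    """(flags, modules tested) for treatment-correlation under a full null."""
    flagged = total = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_offset(seed, 7_000 + rep),
            n_genes=120,
            regions=("A",),
            sexes=("F",),
            modules=[
                PlantedModule(f"m{i}", "A", 30, ("F",), 0.9, 0.0)
                for i in range(4)
            ],
        )
        flags = _flags_for(config)
        flagged += int(flags["thc_correlated"].sum())
        total += len(flags)
    return flagged, total


def moderated_t_null_uniformity(seed: int = 0, n_batches: int = 10) -> int:
    """Batches (2000 null genes, n=12) whose p-values pass a KS test."""
    ok = 0
    for rep in range(1, n_batches + 1):
        config = SimulationConfig(
            seed=_offset(seed, 11_000 + rep),
            n_genes=2000,
            regions=("A",),
            sexes=("F",),
            modules=[],
        )
        study, _ = simulate_study(config)
        table = diffexpr.deg_table(subset_by(study, "A", "F"))
        ok += stats.kstest(table["p"], "uniform").pvalue > 0.01
    return ok


def msea_null_pvalues(
    seed: int = 0, n_sims: int = 100, n_perm: int = 200
) -> list[float]:
    """Permutation p of an unenriched module across null simulations."""
    out = []
    for rep in range(n_sims):
        config = SimulationConfig(
            seed=_offset(seed, 13_000 + rep),
            n_genes=100,
            regions=("A",),
            sexes=("F",),
            modules=[PlantedModule("m1", "A", 20, ("F",))],
            gwas=GwasConfig(n_markers=600, enriched_module=None,
                            signal_strength=0.0),
        )
        study, truth = simulate_study(config)
        markers, mapping, _, ld = simulate_gwas(config, study.gene_ids, truth)
        pruned = gwas.marker_dependency_filter(markers, ld)
        res = gwas.msea(
            truth.module_genes["m1"], mapping, pruned,
            n_perm=n_perm, seed=_offset(seed, 17_000 + rep),
        )
        out.append(res["p"])
    return out


def cognitive_flag_power(seed: int = 0, n_seeds: int = 100) -> int:
    """Runs where a treatment- and memory-coupled module is flagged
    cognitive, at effect sizes delta=1, beta=1.5, sigma=0.3, n=12."""
    hits = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_offset(seed, 19_000 + rep),
            n_genes=80,
            regions=("A",),
            sexes=("F",),
            noise_sd=0.3,
            modules=[
                PlantedModule("m1", "A", 40, ("F",), 0.9, 1.0, {"D1": 1.5})
            ],
        )
        flags = _flags_for(config)
        hits += bool(flags["cognitive"].iloc[0])
    return hits


def coupling_edge_power(
    seed: int = 0, n_seeds: int = 100, weight: float = 0.9
) -> int:
    """Runs where a planted cross-region coupling yields a qualifying edge."""
    hits = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_offset(seed, 23_000 + rep),
            n_genes=80,
            regions=("A", "B"),
            sexes=("F",),
            modules=[
                PlantedModule("ma", "A", 40, ("F",)),
                PlantedModule("mb", "B", 40, ("F",)),
            ],
            couplings=[CrossRegionCoupling("ma", "mb", weight)],
        )
        study, truth = simulate_study(config)
        eig_sets = {}
        for region in ("A", "B"):
            sub = subset_by(study, region, "F")
            eig_sets[region] = cx.module_eigengene(
                sub.expr, _true_partition(sub, truth)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges = module_analysis.cross_module_correlation(
                eig_sets, study, "F"
            )
        edges = edges[
            (edges["module_a"] == "ma") & (edges["module_b"] == "mb")
        ]
        hits += len(module_analysis.qualifying_edges(edges)) > 0
    return hits


def msea_power(seed: int = 0, n_seeds: int = 100, n_perm: int = 200) -> int:
    """Runs where the GWAS-enriched module is called associated."""
    hits = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_offset(seed, 29_000 + rep),
            n_genes=100,
            regions=("A",),
            sexes=("F",),
            modules=[PlantedModule("m1", "A", 20, ("F",))],
            gwas=GwasConfig(n_markers=800, enriched_module="m1",
                            signal_strength=6.0),
        )
        study, truth = simulate_study(config)
        markers, mapping, _, ld = simulate_gwas(config, study.gene_ids, truth)
        pruned = gwas.marker_dependency_filter(markers, ld)
        rng = np.random.default_rng(_offset(seed, 31_000 + rep))
        modules = {"m1": truth.module_genes["m1"]}
        mapped = sorted({g for genes in mapping.values() for g in genes})
        others = [g for g in mapped if g not in set(modules["m1"])]
        for i in range(4):
            modules[f"null{i}"] = list(
                rng.choice(others, min(20, len(others)), replace=False)
            )
        res = gwas.msea_all(
            modules, mapping, pruned, n_perm=n_perm,
            seed=_offset(seed, 37_000 + rep),
        ).set_index("module")
        hits += bool(res.at["m1", "associated"])
    return hits


def hub_rank_power(seed: int = 0, n_seeds: int = 100) -> int:
    """Runs where the planted network hub is the top-ranked key driver."""
    hits = 0
    for rep in range(n_seeds):
        config = SimulationConfig(
            seed=_offset(seed, 41_000 + rep),
            n_genes=150,
            regions=("A",),
            sexes=("F",),
            modules=[PlantedModule("m1", "A", 30, ("F",))],
            network=NetworkConfig(n_nodes=150, hubs={"h": "m1"}),
        )
        study, truth = simulate_study(config)
        network = simulate_network(config, truth)
        res = keydrivers.kda(network, truth.module_genes["m1"])
        (hub,) = truth.hubs
        hits += res.iloc[0]["gene_id"] == hub
    return hits
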