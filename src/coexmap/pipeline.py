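"""End-to-end orchestration with a YAML config and a reproducible layout.

``run_all`` simulates (or loads) a multi-region study, then runs, per
(region, sex): differential expression, coexpression module detection, and
module-trait classification; per sex: the cross-region module map, MSEA
against GWAS markers, and key-driver analysis; plus female-vs-male RRHO
maps per region.  Every stage derives its own seed deterministically from
the global seed by hashing the stage name, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, gwas, keydrivers, module_analysis, rrho
from .datamodel import TraitSchema, write_expression_tsv, write_network_tsv
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

log = logging.getLogger("coexmap")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,
    "simulation": {
        "n_genes": 300,
        "n_animals_per_group": 6,
        "regions": ["PFC", "NAc", "DMS", "Amy", "VTA"],
        "sexes": ["F", "M"],
        "noise_sd": 0.3,
        "treatment_trait_effect": -0.5,
    },
    "deg": {"alpha": 0.05, "lfc_min": 0.4},
    "coexpression": {
        "beta": None,
        "mode": "unsigned",
        "min_module_size": 30,
        "cut_quantile": None,
        "merge_height": 0.25,
    },
    "traits": {"alpha": 0.05},
    "crossregion": {"r_min": 0.5, "alpha": 0.05, "partial_treatment": False},
    "rrho": {"step": None},
    "msea": {
        "p_max": 0.001,
        "n_perm": 200,
        "alpha": 0.05,
        "r2_max": 0.5,
        "window_bp": 50000,
    },
    "kda": {"depth": 1, "min_neighborhood": 5, "alpha": 0.05},
}


def default_planted_modules() -> list[PlantedModule]:
    """The default planted structure behind the synthetic study.

    One module shared by both sexes in NAc (treatment-affected, memory-trait
    coupled, GWAS-enriched, hub-regulated), sex-specific treatment modules
    in DMS/VTA/Amy, a VTA module coupled to the Amy module across regions,
    and a null module in PFC.
    """
    return [
        PlantedModule("nac_shared", "NAc", 40, ("F", "M"), 0.9, 1.0,
                      {"D1": 1.5, "D2": 1.0}),
        PlantedModule("dms_f", "DMS", 40, ("F",), 0.9, 1.0, {"D1": 1.5}),
        PlantedModule("vta_f", "VTA", 40, ("F",), 0.9, 1.0, {"D2": 1.5}),
        PlantedModule("amy_f", "Amy", 40, ("F",), 0.9, 1.0, {}),
        PlantedModule("vta_coupled", "VTA", 30, ("F",), 0.9, 0.0, {}),
        PlantedModule("pfc_null", "PFC", 40, ("F", "M"), 0.9, 0.0, {}),
    ]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def validate_config(config: dict) -> dict:
    """Merge over defaults; unknown keys are rejected with a suggestion."""

    def merge(defaults: dict, given: dict, path: str) -> dict:
        out = deepcopy(defaults)
        for key, value in given.items():
            if key not in defaults:
                hint = difflib.get_close_matches(key, defaults, n=1)
                extra = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ValueError(f"unknown config key {path}{key!r}{extra}")
            if isinstance(defaults[key], dict) and isinstance(value, dict):
                out[key] = merge(defaults[key], value, f"{path}{key}.")
            else:
                out[key] = value
        return out

    return merge(DEFAULT_CONFIG, config or {}, "")


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def build_simulation_config(config: dict) -> SimulationConfig:
    sim = config["simulation"]
    regions = set(sim["regions"])
    modules = [m for m in default_planted_modules() if m.region in regions]
    kept = {m.name for m in modules}
    couplings = [
        c
        for c in [CrossRegionCoupling("amy_f", "vta_coupled", 0.9)]
        if {c.module_a, c.module_b} <= kept
    ]
    gwas_module = "nac_shared" if "nac_shared" in kept else None
    hubs = {"hub": "nac_shared"} if "nac_shared" in kept else {}
    return SimulationConfig(
        seed=stage_seed(config["seed"], "simulate"),
        n_genes=sim["n_genes"],
        n_animals_per_group=sim["n_animals_per_group"],
        regions=tuple(sim["regions"]),
        sexes=tuple(sim["sexes"]),
        noise_sd=sim["noise_sd"],
        treatment_trait_effect=sim["treatment_trait_effect"],
        modules=modules,
        couplings=couplings,
        gwas=GwasConfig(enriched_module=gwas_module,
                        window_bp=config["msea"]["window_bp"]),
        network=NetworkConfig(n_nodes=sim["n_genes"], hubs=hubs),
        schema=TraitSchema(),
    )


class PipelineRunner:
    """Runs stages in dependency order, skipping completed ones."""

    def __init__(self, config: dict, outdir, force: bool = False):
        self.config = validate_config(config)
        self.outdir = Path(outdir)
        self.force = force
        self.manifest: dict = {
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest(),
            "seed": self.config["seed"],
            "stages": {},
        }

    def _stage_dir(self, name: str) -> Path:
        d = self.outdir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _done(self, name: str) -> bool:
        return (self.outdir / name / ".done").exists() and not self.force

    def _mark(self, name: str, t0: float, **counts) -> None:
        (self.outdir / name / ".done").touch()
        self.manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 2),
            **counts,
        }
        log.info("stage %s done (%.1fs) %s", name, time.time() - t0, counts)

    def run(self) -> dict:
        try:
            self._simulate()
            self._deg()
            self._coexpress()
            self._traits()
            self._crossregion()
            self._rrho()
            self._msea()
            self._kda()
            self._report()
        except Exception as exc:  # annotate which stage failed
            raise RuntimeError(
                f"pipeline aborted in stage {getattr(self, '_current', '?')!r}: "
                f"{exc}"
            ) from exc
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        return self.manifest

    # -- stages ---------------------------------------------------------

    def _simulate(self) -> None:
        self._current = "simulate"
        t0 = time.time()
        d = self._stage_dir("inputs")
        sim_config = build_simulation_config(self.config)
        self.sim_config = sim_config
        study, truth = simulate_study(sim_config)
        markers, mapping, gene_spans, ld = simulate_gwas(
            sim_config, study.gene_ids, truth
        )
        network = simulate_network(sim_config, truth)
        self.study, self.truth = study, truth
        self.markers, self.mapping, self.gene_spans, self.ld = (
            markers, mapping, gene_spans, ld,
        )
        self.network = network
        if not self._done("inputs"):
            write_expression_tsv(study.expr, d / "expression.tsv")
            study.design.to_csv(d / "design.tsv", sep="\t", index=False)
            study.traits.to_csv(d / "traits.tsv", sep="\t", index=False)
            markers.data.to_csv(d / "markers.tsv", sep="\t", index=False)
            write_network_tsv(network, d / "network.tsv")
            truth.to_json(d / "truth.json")
            self._mark("inputs", t0, n_samples=len(study.sample_ids),
                       n_genes=len(study.gene_ids), n_markers=len(markers))

    def _strata(self):
        for region in self.sim_config.regions:
            for sex in self.sim_config.sexes:
                yield region, sex

    def _deg(self) -> None:
        self._current = "deg"
        t0 = time.time()
        d = self._stage_dir("deg")
        from .datamodel import subset_by

        params = self.config["deg"]
        self.deg_tables = {}
        for region, sex in self._strata():
            sub = subset_by(self.study, region, sex)
            table = diffexpr.deg_table(
                sub, alpha=params["alpha"], lfc_min=params["lfc_min"]
            )
            self.deg_tables[(region, sex)] = table
            table.to_csv(d / f"{region}_{sex}.tsv", sep="\t", index=False)
        self.interaction_tables = {}
        for region in self.sim_config.regions:
            mask = self.study.design["region"] == region
            from .datamodel import ExpressionMatrix, ExpressionStudy

            design = self.study.design.loc[mask].reset_index(drop=True)
            sub = ExpressionStudy(
                ExpressionMatrix(
                    self.study.expr.data.loc[:, list(design["sample_id"])]
                ),
                design,
                self.study.traits,
                self.study.schema,
            )
            table = diffexpr.interaction_degs(
                sub, alpha=params["alpha"], lfc_min=params["lfc_min"]
            )
            self.interaction_tables[region] = table
            table.to_csv(d / f"interaction_{region}.tsv", sep="\t", index=False)
        if not self._done("deg"):
            self._mark(
                "deg", t0,
                n_deg={f"{r}_{s}": int(t["is_deg"].sum())
                       for (r, s), t in self.deg_tables.items()},
            )

    def _coexpress(self) -> None:
        self._current = "coexpress"
        t0 = time.time()
        d = self._stage_dir("coexpression")
        from .datamodel import subset_by

        params = self.config["coexpression"]
        self.partitions = {}
        self.eigengenes = {}
        self.toms = {}
        for region, sex in self._strata():
            sub = subset_by(self.study, region, sex)
            partition, eigs, tom, adj = coexpression.detect_modules(
                sub.expr,
                beta=params["beta"],
                mode=params["mode"],
                min_module_size=params["min_module_size"],
                cut_quantile=params["cut_quantile"],
                merge_height=params["merge_height"],
            )
            self.partitions[(region, sex)] = partition
            self.eigengenes[(region, sex)] = eigs
            self.toms[(region, sex)] = tom
            partition.to_frame().to_csv(
                d / f"{region}_{sex}.partition.tsv", sep="\t", index=False
            )
            eigs.data.to_csv(d / f"{region}_{sex}.eigengenes.tsv", sep="\t")
        if not self._done("coexpression"):
            self._mark(
                "coexpression", t0,
                n_modules={
                    f"{r}_{s}": len([m for m in p.labels if m != "grey"])
                    for (r, s), p in self.partitions.items()
                },
            )

    def _traits(self) -> None:
        self._current = "traits"
        t0 = time.time()
        d = self._stage_dir("traits")
        alpha = self.config["traits"]["alpha"]
        frames, flag_frames = [], []
        for region, sex in self._strata():
            profile = module_analysis.module_trait_correlation(
                self.eigengenes[(region, sex)], self.study, region, sex
            )
            profile = module_analysis.classify_modules(
                profile, self.study.schema, alpha=alpha
            )
            frames.append(profile.table)
            flag_frames.append(profile.flags)
        self.profile_table = pd.concat(frames, ignore_index=True)
        self.flags = pd.concat(flag_frames, ignore_index=True)
        self.profile_table.to_csv(d / "profile.tsv", sep="\t", index=False)
        self.flags.to_csv(d / "flags.tsv", sep="\t", index=False)
        if not self._done("traits"):
            self._mark(
                "traits", t0,
                n_thc_correlated=int(self.flags["thc_correlated"].sum()),
                n_cognitive=int(self.flags["cognitive"].sum()),
            )

    def _crossregion(self) -> None:
        self._current = "crossregion"
        t0 = time.time()
        d = self._stage_dir("crossregion")
        params = self.config["crossregion"]
        self.edges = {}
        self.interconnected = {}
        for sex in self.sim_config.sexes:
            eig_sets = {
                region: self.eigengenes[(region, sex)]
                for region in self.sim_config.regions
            }
            edges = module_analysis.cross_module_correlation(
                eig_sets, self.study, sex,
                partial_treatment=params["partial_treatment"],
            )
            sex_flags = self.flags[self.flags["sex"] == sex]
            inter = module_analysis.interconnected_modules(
                edges, sex_flags, r_min=params["r_min"], alpha=params["alpha"]
            )
            qual = module_analysis.qualifying_edges(
                edges, params["r_min"], params["alpha"]
            )
            tally = module_analysis.connectivity_tally(qual)
            self.edges[sex] = edges
            self.interconnected[sex] = inter
            edges.to_csv(d / f"{sex}.edges.tsv", sep="\t", index=False)
            tally.to_csv(d / f"{sex}.tally.tsv", sep="\t", index=False)
            module_analysis.sankey_export(tally, d / f"{sex}.sankey.json")
        if not self._done("crossregion"):
            self._mark(
                "crossregion", t0,
                n_interconnected={s: len(v) for s, v in
                                  self.interconnected.items()},
            )

    def _rrho(self) -> None:
        self._current = "rrho"
        t0 = time.time()
        d = self._stage_dir("rrho")
        step = self.config["rrho"]["step"]
        n_maps = 0
        if set(self.sim_config.sexes) >= {"F", "M"}:
            for region in self.sim_config.regions:
                sig_f = rrho.make_signature(self.deg_tables[(region, "F")])
                sig_m = rrho.make_signature(self.deg_tables[(region, "M")])
                rmap = rrho.rrho_map(sig_f, sig_m, step=step)
                rrho.write_rrho_map(rmap, str(d / f"{region}_F_vs_M"))
                n_maps += 1
        if not self._done("rrho"):
            self._mark("rrho", t0, n_maps=n_maps)

    def _module_gene_sets(self, sex: str) -> dict[str, list[str]]:
        out = {}
        for region in self.sim_config.regions:
            partition = self.partitions[(region, sex)]
            for module in partition.labels:
                if module == "grey":
                    continue
                out[f"{region}:{module}"] = partition.members(module)
        return out

    def _msea(self) -> None:
        self._current = "msea"
        t0 = time.time()
        d = self._stage_dir("msea")
        params = self.config["msea"]
        pruned = gwas.marker_dependency_filter(
            self.markers, self.ld, r2_max=params["r2_max"]
        )
        pruned.data.to_csv(d / "pruned_markers.tsv", sep="\t", index=False)
        self.msea_results = {}
        self.overlaps = {}
        for sex in self.sim_config.sexes:
            modules = self._module_gene_sets(sex)
            res = gwas.msea_all(
                modules, self.mapping, pruned,
                n_perm=params["n_perm"],
                seed=stage_seed(self.config["seed"], f"msea:{sex}"),
                alpha=params["alpha"],
            )
            res.to_csv(d / f"{sex}.tsv", sep="\t", index=False)
            self.msea_results[sex] = res
            associated = set(res.loc[res["associated"], "module"])
            sex_flags = self.flags[self.flags["sex"] == sex]
            thc = {
                f"{row.region}:{row.module}"
                for row in sex_flags.itertuples()
                if row.thc_correlated
            }
            inter = {
                f"{region}:{module}"
                for region, module in self.interconnected.get(sex, set())
            }
            self.overlaps[sex] = {
                "n_associated": len(associated),
                "overlap_thc_pct": gwas.overlap_fraction(associated, thc)
                if associated else float("nan"),
                "overlap_thc_plus_interconnected_pct": gwas.overlap_fraction(
                    associated, thc | inter
                ) if associated else float("nan"),
            }
        with open(d / "overlap.json", "w") as fh:
            json.dump(self.overlaps, fh, indent=1, default=str)
        if not self._done("msea"):
            self._mark("msea", t0, overlaps=self.overlaps)

    def _kda(self) -> None:
        self._current = "kda"
        t0 = time.time()
        d = self._stage_dir("kda")
        params = self.config["kda"]
        self.kd_results = {}
        for sex in self.sim_config.sexes:
            res = self.msea_results[sex]
            modules = self._module_gene_sets(sex)
            for name in sorted(res.loc[res["associated"], "module"]):
                genes = modules[name]
                on_network = set(genes) & self.network.nodes
                if not on_network:
                    continue
                kd = keydrivers.kda(
                    self.network, genes,
                    depth=params["depth"],
                    min_neighborhood=params["min_neighborhood"],
                    alpha=params["alpha"],
                )
                self.kd_results[(sex, name)] = kd
                safe = name.replace(":", "_")
                kd.to_csv(d / f"{sex}_{safe}.tsv", sep="\t", index=False)
        sexes = list(self.sim_config.sexes)
        self.shared_kds = pd.DataFrame(columns=["gene_id", "p_a", "p_b"])
        if len(sexes) >= 2:
            def kd_union(sex):
                frames = [kd for (s, _), kd in self.kd_results.items() if s == sex]
                if not frames:
                    return pd.DataFrame(
                        columns=["gene_id", "p", "fdr", "is_key_driver"]
                    )
                allkd = pd.concat(frames, ignore_index=True)
                return (
                    allkd.sort_values("p")
                    .drop_duplicates("gene_id")
                    .reset_index(drop=True)
                )

            self.shared_kds = keydrivers.shared_key_drivers(
                kd_union(sexes[0]), kd_union(sexes[1])
            )
        self.shared_kds.to_csv(d / "shared.tsv", sep="\t", index=False)
        # subnetwork around the shared key drivers, annotated by role
        if len(self.shared_kds):
            module_union = set()
            for (sex, name) in self.kd_results:
                module_union |= set(self._module_gene_sets(sex)[name])
            nodes, edges = keydrivers.extract_subnetwork(
                self.network, list(self.shared_kds["gene_id"]), module_union,
                depth=params["depth"],
            )
            nodes.to_csv(d / "subnetwork.nodes.tsv", sep="\t", index=False)
            edges.to_csv(d / "subnetwork.edges.tsv", sep="\t", index=False)
        if not self._done("kda"):
            self._mark(
                "kda", t0,
                n_kd_analyses=len(self.kd_results),
                n_shared_kds=len(self.shared_kds),
            )

    def _report(self) -> None:
        self._current = "report"
        t0 = time.time()
        self._stage_dir("report")
        report: dict = {"strata": {}, "per_sex": {}}
        for region, sex in self._strata():
            key = f"{region}_{sex}"
            flags = self.flags[
                (self.flags["region"] == region) & (self.flags["sex"] == sex)
            ]
            report["strata"][key] = {
                "n_degs": int(self.deg_tables[(region, sex)]["is_deg"].sum()),
                "n_modules": int(len(flags)),
                "n_thc_correlated": int(flags["thc_correlated"].sum()),
                "n_cognitive": int(flags["cognitive"].sum()),
            }
        for region in self.sim_config.regions:
            report["strata"].setdefault(f"interaction_{region}", {})[
                "n_interaction_degs"
            ] = int(self.interaction_tables[region]["is_deg"].sum())
        for sex in self.sim_config.sexes:
            kd_genes = sorted(
                {
                    g
                    for (s, _), kd in self.kd_results.items()
                    if s == sex
                    for g in kd.loc[kd["is_key_driver"], "gene_id"]
                }
            )
            report["per_sex"][sex] = {
                "n_interconnected": len(self.interconnected.get(sex, set())),
                **self.overlaps.get(sex, {}),
                "n_key_drivers": len(kd_genes),
            }
        report["shared_key_drivers"] = list(self.shared_kds["gene_id"])
        self.report = report
        with open(self.outdir / "report" / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        if not self._done("report"):
            self._mark("report", t0)


def run_all(config: dict, outdir, force: bool = False) -> dict:
    runner = PipelineRunner(config, outdir, force=force)
    runner.run()
    return runner.report
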