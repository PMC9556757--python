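import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmap import coexpression as cx
from coexmap.datamodel import ExpressionMatrix, subset_by
from coexmap.simulate import PlantedModule, SimulationConfig, simulate_study


def _expr(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes,
                     columns=[f"s{i}" for i in range(values.shape[1])])
    )


def _true_labels(gene_ids, truth):
    return [
        next((m for m, gl in truth.module_genes.items() if g in gl), "bg")
        for g in gene_ids
    ]


class TestCorrelation:
    def test_identical_and_negated_genes(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        corr = cx.correlation_matrix(_expr([base, base, -base]))
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        corr = cx.correlation_matrix(
            _expr([[1, 2, 3, 4], [1, 3, 2, 4], [0, 1, 0, 2]])
        )
        assert corr.iloc[0, 1] == pytest.approx(0.8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            cx.correlation_matrix(_expr([[1, 2], [2, 1]]))

    def test_zero_variance_genes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = cx.correlation_matrix(
                _expr([[1, 2, 3], [5, 5, 5], [3, 1, 2]])
            )
        assert list(corr.index) == ["g0", "g2"]


class TestTom:
    def test_two_node_saturated_edge(self):
        adj = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"),
                           columns=list("ab"))
        tom = cx.tom_similarity(adj)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_is_zero(self):
        adj = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                           columns=list("abc"))
        adj.iloc[1, 2] = adj.iloc[2, 1] = 0.5
        tom = cx.tom_similarity(adj)
        assert tom.iloc[0, 1] == 0.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        tom = cx.tom_similarity(adj).to_numpy()
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                expected = (shared + a[i, j]) / (
                    min(k[i], k[j]) + 1 - a[i, j]
                )
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_adjacency_rejected(self):
        adj = pd.DataFrame([[0.0, 1.5], [1.5, 0.0]], index=list("ab"),
                           columns=list("ab"))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            cx.tom_similarity(adj)


class TestSoftThreshold:
    def _hub_structured_corr(self, seed):
        # several module sizes + per-gene loadings give the heterogeneous
        # connectivity spectrum a scale-free fit needs
        config = SimulationConfig(
            seed=seed, n_genes=500, n_animals_per_group=12,
            regions=("A",), sexes=("F",),
            modules=[
                PlantedModule(f"m{i}", "A", size, ("F",), 0.9, 0.0,
                              loading_range=(0.25, 1.0))
                for i, size in enumerate((80, 60, 50, 40, 30))
            ],
        )
        study, _ = simulate_study(config)
        return cx.correlation_matrix(subset_by(study, "A", "F").expr)

    def test_reaches_target_on_hub_structured_data(self):
        hits = 0
        for seed in range(10):
            corr = self._hub_structured_corr(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, fit = cx.pick_soft_threshold(corr)
            hits += bool((fit["r2"] >= 0.8).any())
        assert hits >= 8

    def test_single_factor_data_takes_warning_path(self):
        # one global factor gives every gene the same connectivity: no
        # power-law fit is possible, so selection falls back with a warning
        rng = np.random.default_rng(0)
        f = rng.normal(size=24)
        rows = 0.9 * np.outer(np.ones(150), f) + rng.normal(0, 0.3, (150, 24))
        corr = cx.correlation_matrix(_expr(rows))
        with pytest.warns(UserWarning, match="falling back"):
            params, fit = cx.pick_soft_threshold(corr)
        assert params.beta == 6

    def test_user_override_bypasses_selection(self):
        params = cx.AdjacencyParams(beta=6)
        assert params.beta == 6
        with pytest.raises(ValueError):
            cx.AdjacencyParams(beta=0)


class TestClusterAndCut:
    def test_recovers_three_planted_blocks(self, planted_study):
        study, truth = planted_study
        sub = subset_by(study, "A", "F")
        corr = cx.correlation_matrix(sub.expr)
        tom = cx.tom_similarity(cx.adjacency(corr, cx.AdjacencyParams(beta=6)))
        partition, _ = cx.cluster_and_cut(tom)
        labels = [m for m in partition.labels if m != cx.GREY]
        assert len(labels) == 3
        ari = adjusted_rand_score(
            _true_labels(list(tom.index), truth),
            [partition.assignment[g] for g in tom.index],
        )
        assert ari >= 0.9

    def test_noise_data_is_mostly_grey(self):
        grey_ok = 0
        for seed in range(10):
            config = SimulationConfig(
                seed=seed, n_genes=150, n_animals_per_group=12,
                regions=("A",), sexes=("F",), modules=[],
            )
            study, _ = simulate_study(config)
            sub = subset_by(study, "A", "F")
            corr = cx.correlation_matrix(sub.expr)
            tom = cx.tom_similarity(
                cx.adjacency(corr, cx.AdjacencyParams(beta=6))
            )
            partition, _ = cx.cluster_and_cut(tom)
            grey_ok += partition.sizes().get(cx.GREY, 0) >= 0.8 * 150
        assert grey_ok >= 8

    def test_min_size_one_disables_grey_rule(self, planted_study):
        study, _ = planted_study
        sub = subset_by(study, "A", "F")
        corr = cx.correlation_matrix(sub.expr)
        tom = cx.tom_similarity(cx.adjacency(corr, cx.AdjacencyParams(beta=6)))
        partition, _ = cx.cluster_and_cut(tom, min_module_size=1)
        assert cx.GREY not in partition.sizes()

    def test_min_size_beyond_n_genes_rejected(self, planted_study):
        study, _ = planted_study
        sub = subset_by(study, "A", "F")
        corr = cx.correlation_matrix(sub.expr)
        tom = cx.tom_similarity(cx.adjacency(corr, cx.AdjacencyParams(beta=6)))
        with pytest.raises(ValueError, match="min_module_size"):
            cx.cluster_and_cut(tom, min_module_size=10_000)


class TestEigengene:
    def test_identical_genes_fully_explained(self):
        base = np.array([1.0, -1.0, 2.0, 0.0])
        expr = _expr([base, base, base])
        part = cx.ModulePartition({"g0": "m", "g1": "m", "g2": "m"})
        eigs = cx.module_eigengene(expr, part)
        assert eigs.variance_explained["m"] == pytest.approx(1.0)
        z = (base - base.mean()) / base.std(ddof=1)
        direction = eigs.data.loc["m"].to_numpy()
        assert abs(np.corrcoef(direction, z)[0, 1]) == pytest.approx(1.0)

    def test_orientation_follows_module_mean(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        expr = _expr([base + rng.normal(0, 0.1, 10) for _ in range(5)])
        part = cx.ModulePartition({f"g{i}": "m" for i in range(5)})
        eig = cx.module_eigengene(expr, part).data.loc["m"]
        mean_profile = expr.values.mean(axis=0)
        assert np.corrcoef(eig, mean_profile)[0, 1] > 0
        flipped = cx.module_eigengene(
            ExpressionMatrix(-expr.data), part
        ).data.loc["m"]
        assert np.corrcoef(flipped, -mean_profile)[0, 1] > 0

    def test_planted_factor_recovered(self):
        config = SimulationConfig(
            seed=3, n_genes=60, n_animals_per_group=12,
            regions=("A",), sexes=("F",),
            modules=[PlantedModule("m1", "A", 40, ("F",), 0.9, 0.0)],
        )
        study, truth = simulate_study(config)
        sub = subset_by(study, "A", "F")
        part = cx.ModulePartition(
            {g: ("m1" if g in truth.module_genes["m1"] else cx.GREY)
             for g in sub.gene_ids}
        )
        eig = cx.module_eigengene(sub.expr, part).data.loc["m1"]
        f = truth.factors.loc[
            sub.design.set_index("sample_id").loc[eig.index, "animal_id"],
            "m1",
        ]
        assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.9

    def test_singleton_module_warns(self):
        expr = _expr(np.random.default_rng(0).normal(size=(2, 6)))
        part = cx.ModulePartition({"g0": "m", "g1": cx.GREY})
        with pytest.warns(UserWarning, match="single gene"):
            cx.module_eigengene(expr, part)


class TestMerge:
    def test_shared_factor_modules_merge(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=20)
        rows = [f * 0.9 + rng.normal(0, 0.2, 20) for _ in range(10)]
        expr = _expr(rows)
        part = cx.ModulePartition(
            {f"g{i}": ("a" if i < 5 else "b") for i in range(10)}
        )
        merged, eigs = cx.merge_close_modules(expr, part)
        assert len([m for m in merged.labels if m != cx.GREY]) == 1

    def test_orthogonal_factors_stay_separate(self):
        rng = np.random.default_rng(2)
        f1, f2 = rng.normal(size=(2, 20))
        rows = [f1 + rng.normal(0, 0.2, 20) for _ in range(5)] + [
            f2 + rng.normal(0, 0.2, 20) for _ in range(5)
        ]
        part = cx.ModulePartition(
            {f"g{i}": ("a" if i < 5 else "b") for i in range(10)}
        )
        merged, _ = cx.merge_close_modules(_expr(rows), part)
        assert len([m for m in merged.labels if m != cx.GREY]) == 2

    def test_zero_merge_height_is_identity(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(10, 12))
        part = cx.ModulePartition(
            {f"g{i}": ("a" if i < 5 else "b") for i in range(10)}
        )
        merged, _ = cx.merge_close_modules(_expr(rows), part, merge_height=0.0)
        assert len([m for m in merged.labels if m != cx.GREY]) == 2


class TestLabels:
    def test_palette_assigned_by_decreasing_size(self):
        assignment = (
            {f"a{i}": "x" for i in range(50)}
            | {f"b{i}": "y" for i in range(40)}
            | {f"c{i}": "z" for i in range(30)}
        )
        labeled = cx.label_modules(cx.ModulePartition(assignment))
        sizes = labeled.sizes()
        assert sizes == {"turquoise": 50, "blue": 40, "brown": 30}

    def test_relabeling_is_idempotent(self):
        assignment = {f"a{i}": "x" for i in range(5)} | {
            f"b{i}": "y" for i in range(3)
        }
        once = cx.label_modules(cx.ModulePartition(assignment))
        twice = cx.label_modules(once)
        assert once.assignment == twice.assignment

    def test_palette_exhaustion_falls_back_to_numbers(self):
        n = len(cx.MODULE_COLORS) + 2
        assignment = {f"g{i}": f"m{i}" for i in range(n)}
        labeled = cx.label_modules(cx.ModulePartition(assignment))
        assert f"module{n}" in labeled.sizes()


class TestTopEdges:
    def _tom(self):
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 0.9, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        return pd.DataFrame(a, index=genes, columns=genes)

    def test_small_module_returns_all_edges(self):
        tom = self._tom()
        part = cx.ModulePartition({g: "m" for g in tom.index[:5]})
        edges = cx.top_edges(tom, part, "m", k=100)
        assert len(edges) == 10
        assert (edges["tom_weight"].diff().dropna() <= 1e-12).all()

    def test_ties_break_lexicographically(self):
        genes = [f"g{i}" for i in range(4)]
        tom = pd.DataFrame(0.5, index=genes, columns=genes)
        part = cx.ModulePartition({g: "m" for g in genes})
        edges = cx.top_edges(tom, part, "m", k=3)
        assert edges[["gene_a", "gene_b"]].values.tolist() == [
            ["g0", "g1"], ["g0", "g2"], ["g0", "g3"],
        ]

    def test_missing_module_rejected(self):
        tom = self._tom()
        part = cx.ModulePartition({g: "m" for g in tom.index})
        with pytest.raises(ValueError, match="nope"):
            cx.top_edges(tom, part, "nope")


def test_pipeline_is_deterministic(planted_study):
    study, _ = planted_study
    sub = subset_by(study, "A", "F")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = cx.detect_modules(sub.expr)
        b = cx.detect_modules(sub.expr)
    assert a[0].assignment == b[0].assignment
    pd.testing.assert_frame_equal(a[1].data, b[1].data)
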