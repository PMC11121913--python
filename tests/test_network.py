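import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnetox.network import (
    CorrelationNetworkModel,
    build_network,
    filter_edges,
    find_hubs,
    pearson_r,
)
from mirnetox.simulate import SimulationConfig, simulate
from mirnetox.targets import CandidateTargetPair


class TestPearson:
    def test_exact_anticorrelation(self):
        r, p = pearson_r([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-6)

    def test_self_correlation(self):
        r, _ = pearson_r([1, 2, 5], [1, 2, 5])
        assert r == 1.0

    def test_hand_computed_case(self):
        # sum dx*dy = 3, sum dx^2 = sum dy^2 = 5 -> r = 0.6;
        # t = 0.6 sqrt(2/0.64), p two-sided on 2 df
        r, p = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        assert p == pytest.approx(2 * stats.t.sf(t, 2))

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.normal(size=(2, 8))
            r, p = pearson_r(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pearson_r([1, 2, 3], [1, 2])


class TestFilterEdges:
    @pytest.mark.parametrize(
        "r, fdr, kept",
        [(-0.99, 0.01, True), (0.99, 1e-6, False), (-0.5, 0.05, False)],
    )
    def test_sign_and_fdr_rules_strict(self, r, fdr, kept):
        edges = pd.DataFrame({"mirna": ["m"], "gene": ["g"], "r": [r],
                              "p_value": [fdr], "fdr": [fdr]})
        assert (len(filter_edges(edges)) == 1) is kept


class TestBuildNetwork:
    def test_shared_mirna_degrees(self):
        edges = pd.DataFrame(
            {"mirna": ["m1"] * 3, "gene": ["g1", "g2", "g3"],
             "r": [-0.9] * 3, "fdr": [0.01] * 3}
        )
        g = build_network(edges)
        assert g.nodes["m1"]["degree"] == 3
        assert sum(1 for _, d in g.nodes(data=True) if d["role"] == "mRNA") == 3

    def test_empty_edges(self):
        g = build_network(pd.DataFrame(columns=["mirna", "gene", "r", "fdr"]))
        assert g.number_of_nodes() == 0

    def test_shared_gene_degree(self):
        edges = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["g1", "g1"],
             "r": [-0.9, -0.8], "fdr": [0.01, 0.02]}
        )
        assert build_network(edges).nodes["g1"]["degree"] == 2

    def test_bipartite_violation_rejected(self):
        edges = pd.DataFrame(
            {"mirna": ["m1", "x"], "gene": ["x", "g1"],
             "r": [-0.9, -0.9], "fdr": [0.01, 0.01]}
        )
        with pytest.raises(ValueError, match="both sides"):
            build_network(edges)

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(3)
        rows = {(f"m{rng.integers(6)}", f"g{rng.integers(15)}") for _ in range(30)}
        edges = pd.DataFrame(
            [(m, g, -0.9, 0.01) for m, g in rows],
            columns=["mirna", "gene", "r", "fdr"],
        )
        g = build_network(edges)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


def hub_structure_network():
    """Bipartite network with the published hub-degree structure:
    seven hub miRNAs of degrees 66/24/21/20/16/16/14 over 134 unique
    targets, plus 27 low-degree miRNAs contributing the remaining 135
    of 312 edges."""
    degrees = [66, 24, 21, 20, 16, 16, 14]
    rows = []
    fresh = 0
    for h, deg in enumerate(degrees):
        n_fresh = min(deg, 134 - fresh)
        for k in range(n_fresh):
            rows.append((f"hub{h}", f"g{fresh + k}"))
        for k in range(deg - n_fresh):  # reuse hub0's targets
            rows.append((f"hub{h}", f"g{k}"))
        fresh += n_fresh
    for m in range(27):  # 27 x 5 = 135 non-hub edges on separate genes
        for k in range(5):
            rows.append((f"low{m}", f"g{134 + (5 * m + k) % 99}"))
    edges = pd.DataFrame(
        [(m, g, -0.95, 0.01) for m, g in rows], columns=["mirna", "gene", "r", "fdr"]
    )
    assert len(edges) == 312
    return build_network(edges)


class TestHubs:
    def test_published_degree_structure(self):
        report = find_hubs(hub_structure_network(), min_degree=10)
        assert [d for _, d in report.hubs] == [66, 24, 21, 20, 16, 16, 14]
        assert report.hub_edge_count == 177
        assert report.total_edge_count == 312
        assert report.hub_edge_fraction == pytest.approx(177 / 312)
        assert report.hub_target_count == 134

    def test_no_hubs_below_threshold(self):
        edges = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["g1", "g2"],
             "r": [-0.9, -0.9], "fdr": [0.01, 0.01]}
        )
        report = find_hubs(build_network(edges), min_degree=10)
        assert report.hubs == [] and report.hub_edge_fraction == 0.0

    def test_degree_exactly_at_threshold_included(self):
        edges = pd.DataFrame(
            {"mirna": ["m1"] * 10, "gene": [f"g{i}" for i in range(10)],
             "r": [-0.9] * 10, "fdr": [0.01] * 10}
        )
        report = find_hubs(build_network(edges), min_degree=10)
        assert report.hubs == [("m1", 10)]

    def test_hub_edge_count_equals_incident_edges(self):
        g = hub_structure_network()
        report = find_hubs(g, min_degree=10)
        hub_names = {m for m, _ in report.hubs}
        incident = sum(1 for u, v in g.edges() if u in hub_names or v in hub_names)
        assert report.hub_edge_count == incident


def candidate_pairs_with_decoys(mr, truth, regimen, n_total, seed):
    planted = {(m, g) for m, g, _ in truth.planted_pairs[regimen]}
    de_mi = sorted(truth.de_mirnas[regimen])
    planted_genes = {g for _, g in planted}
    others = [g for g in mr.feature_ids if g not in planted_genes]
    rng = np.random.default_rng(seed)
    decoys = set()
    while len(decoys) < n_total - len(planted):
        decoys.add((de_mi[rng.integers(len(de_mi))], others[rng.integers(len(others))]))
    return [CandidateTargetPair(m, g, 1, "table") for m, g in sorted(planted | decoys)], planted


class TestPlantedRecovery:
    def test_precision_and_recall_under_strong_contrast(self):
        # 6 samples, beta=1, phi=0.1, 40 planted among 400 candidates;
        # the planted contrast is strong enough that true pair
        # correlations reach the -0.95..-0.99 band the filter targets
        tp_total = kept_total = 0
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_mirna=200, n_mrna=300, treatment_effect=5.0, dispersion=0.1,
                repression_strength=1.0, n_planted_pairs=40, regimens=("pre",),
                seed=seed,
            )
            mi, mr, sheet, truth = simulate(cfg)
            pairs, planted = candidate_pairs_with_decoys(mr, truth, "pre", 400, seed + 1000)
            res = CorrelationNetworkModel(mi, mr, sheet, pairs, regimen="pre").fit()
            kept = {(r.mirna, r.gene) for r in res.retained.itertuples()}
            assert len(kept & planted) / 40 >= 0.5
            tp_total += len(kept & planted)
            kept_total += len(kept)
        assert tp_total / kept_total >= 0.8

    def test_stored_r_reproducible_from_expression(self):
        cfg = SimulationConfig(
            n_mirna=50, n_mrna=60, treatment_effect=5.0, dispersion=0.1,
            n_planted_pairs=10, regimens=("pre",), seed=4,
        )
        mi, mr, sheet, truth = simulate(cfg)
        pairs, _ = candidate_pairs_with_decoys(mr, truth, "pre", 30, 99)
        model = CorrelationNetworkModel(mi, mr, sheet, pairs, regimen="pre")
        res = model.fit()
        mi_expr = model._expression(mi)
        mr_expr = model._expression(mr)
        sub = sheet.subset(regimen="pre")
        for row in res.retained.itertuples():
            x = mi_expr.loc[row.mirna, sub.mirna_libraries()]
            y = mr_expr.loc[row.gene, sub.mrna_libraries()]
            r, _ = pearson_r(x, y)
            assert r == pytest.approx(row.r, abs=1e-12)

    def test_empty_pair_list(self, recovery_sim):
        _, (mi, mr, sheet, _) = recovery_sim
        res = CorrelationNetworkModel(mi, mr, sheet, [], regimen="co").fit()
        assert len(res.edges) == 0 and res.graph.number_of_nodes() == 0

    def test_too_few_samples_rejected(self, recovery_sim):
        _, (mi, mr, sheet, _) = recovery_sim
        from mirnetox.io import SampleSheet
        thin = SampleSheet(sheet.subset(regimen="co").records[:2])
        with pytest.raises(ValueError, match="at least 3"):
            CorrelationNetworkModel(mi, mr, thin, []).fit()
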