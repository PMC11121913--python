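import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from mirnetox.de import (
    DifferentialExpressionModel,
    bh_adjust,
    call_de,
    cpm_normalize,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_test,
    filter_low_expression,
)
from mirnetox.io import CountMatrix
from mirnetox.simulate import SimulationConfig, simulate


def make_matrix(counts, library_sizes=None):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"f{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
        library_sizes=None if library_sizes is None else np.asarray(library_sizes),
    )


class TestCpm:
    def test_formula(self):
        m = make_matrix([[5], [995]], library_sizes=[1000])
        assert cpm_normalize(m).iloc[0, 0] == 5000.0

    def test_all_zero_feature(self):
        m = make_matrix([[0, 0], [10, 20]])
        assert (cpm_normalize(m).iloc[0] == 0).all()

    def test_column_sums_conserved_at_1e6(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 100, size=(30, 4)))
        assert np.allclose(cpm_normalize(m).sum(axis=0), 1e6)


class TestLowExpressionFilter:
    def test_threshold_from_smallest_library(self):
        # libraries (1000, 2000): t = 5/1000*1e6 = 5000 CPM; feature 0
        # sits below t in both samples (4000 and 4500 CPM) -> removed
        m = make_matrix([[4, 9], [996, 1991]], library_sizes=[1000, 2000])
        assert filter_low_expression(m) == ["f1"]

    def test_all_zero_feature_removed(self):
        m = make_matrix([[0, 0, 0], [50, 60, 70]])
        assert "f0" not in filter_low_expression(m)

    def test_boundary_half_of_six_samples_retained(self):
        # CPM >= t in exactly 3 of 6 samples: ceil(0.5*6) = 3 -> retained
        lib = 1_000_000
        t_counts = 5  # t corresponds to exactly 5 raw counts here
        row = [t_counts, t_counts, t_counts, 0, 0, 0]
        filler = [lib - r for r in row]
        m = make_matrix([row, filler], library_sizes=[lib] * 6)
        assert "f0" in filter_low_expression(m)


class TestEqualization:
    def test_geometric_mean_target_with_equal_libraries_is_identity(self):
        counts = np.array([[3, 8], [5, 5]])
        out = equalize_library_sizes(counts, np.array([1000, 1000]))
        assert np.array_equal(out, counts)

    def test_scaling_direction(self):
        counts = np.array([[100, 100]])
        out = equalize_library_sizes(counts, np.array([1000, 4000]))
        # geometric mean 2000: small library scaled up, large scaled down
        assert out[0, 0] == 200 and out[0, 1] == 50


class TestDispersionEstimator:
    def test_identical_replicates_give_zero(self):
        m = make_matrix(np.tile([[10], [50], [200]], (1, 4)))
        assert estimate_common_dispersion(m, ["a", "a", "b", "b"]).phi == 0.0

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(np.log(100), 0.5, 200)
        counts = rng.poisson(mu[:, None], size=(200, 6))
        m = make_matrix(counts, library_sizes=[counts.sum(0).max()] * 6)
        est = estimate_common_dispersion(m, ["a"] * 3 + ["b"] * 3)
        assert est.phi < 0.05

    def test_recovers_moderate_dispersion(self):
        rng = np.random.default_rng(2)
        phi = 0.4
        mu = rng.lognormal(np.log(100), 0.5, 300)
        lam = rng.gamma(1 / phi, phi * mu[:, None], size=(300, 6))
        counts = rng.poisson(lam)
        m = make_matrix(counts, library_sizes=[counts.sum(0).max()] * 6)
        est = estimate_common_dispersion(m, ["a"] * 3 + ["b"] * 3)
        assert 0.2 <= est.phi <= 0.6

    def test_single_sample_group_rejected(self):
        m = make_matrix([[1, 2, 3]])
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_common_dispersion(m, ["a", "a", "b"])


def enumeration_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Independent brute-force conditional exact test (linear-space)."""
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    x = np.arange(total + 1)
    if phi == 0:
        p_split = np.exp(
            gammaln(total + 1) - gammaln(x + 1) - gammaln(total - x + 1)
        ) * (n_a / (n_a + n_b)) ** x * (n_b / (n_a + n_b)) ** (total - x)
    else:
        ra, rb = n_a / phi, n_b / phi
        w = np.exp(
            gammaln(x + ra) - gammaln(x + 1) - gammaln(ra)
            + gammaln(total - x + rb) - gammaln(total - x + 1) - gammaln(rb)
        )
        p_split = w / w.sum()
    obs = p_split[sum_a]
    return min(1.0, p_split[p_split <= obs * (1 + 1e-10)].sum())


class TestExactTest:
    def test_balanced_split_is_modal(self):
        # 5 vs 5 with phi=0: the observed split is the binomial mode
        assert exact_test([5], [5], phi=0.0) == 1.0

    def test_extreme_split_matches_binomial_tail(self):
        p = exact_test([0], [20], phi=0.0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_identical_groups_p_one(self):
        for phi in (0.0, 0.1, 1.0):
            assert exact_test([3, 4, 5], [3, 4, 5], phi) == 1.0

    def test_zero_total_convention(self):
        assert exact_test([0, 0], [0, 0], phi=0.5) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.4, 2.0])
    def test_agrees_with_enumeration_oracle(self, phi):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_a, n_b = rng.integers(2, 5, size=2)
            total = int(rng.integers(1, 51))
            sum_a = int(rng.integers(0, total + 1))
            a = [sum_a] + [0] * (n_a - 1)
            b = [total - sum_a] + [0] * (n_b - 1)
            expected = enumeration_oracle(sum_a, total - sum_a, n_a, n_b, phi)
            assert exact_test(a, b, phi) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=4),
        st.lists(st.integers(0, 50), min_size=2, max_size=4),
        st.sampled_from([0.0, 0.1, 1.0]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_group_swap_symmetry(self, a, b, phi):
        assert exact_test(a, b, phi) == pytest.approx(exact_test(b, a, phi), abs=1e-12)


class TestBhAdjust:
    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_up_definition(self, pvals):
        q = bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            expected[i] = running
        assert q == pytest.approx(expected, abs=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)


class TestCallDe:
    def test_strict_thresholds(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "log2fc": [1.0, 0.6, -0.61],
                "fdr": [0.05, 0.01, 0.01],
            }
        )
        out = call_de(records)
        assert list(out["significant"]) == [False, False, True]
        assert list(out["direction"]) == ["up", "up", "down"]


class TestModel:
    def test_label_swap_negates_log2fc_keeps_p(self, recovery_sim):
        _, (mirna, _, sheet, _) = recovery_sim
        sub = sheet.subset(regimen="co")
        sel = mirna.subset_samples(sub.mirna_libraries())
        fwd = DifferentialExpressionModel(sel, sub.conditions()).fit()
        rev = DifferentialExpressionModel(
            sel, sub.conditions(), contrast=("treated", "control")
        ).fit()
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"], atol=1e-12)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-12)

    def test_recovers_planted_mirnas(self, recovery_sim):
        _, (mirna, _, sheet, truth) = recovery_sim
        res = DifferentialExpressionModel.from_sample_sheet(mirna, sheet, "pre").fit()
        planted = set(truth.de_mirnas["pre"])
        called = res.significant_ids()
        assert len(called & planted) / len(planted) >= 0.9

    def test_directional_count_recovery_at_scale(self):
        # planted 122 down + 83 up among 1500 miRNAs, strong effect:
        # direction-resolved true positives within 5% of the planted
        # counts and overall precision >= 0.9
        cfg = SimulationConfig(
            n_mirna=1500, n_mrna=50, n_up_mirna=83, n_down_mirna=122,
            treatment_effect=3.0, dispersion=0.1, n_planted_pairs=10,
            regimens=("co",), seed=11,
        )
        mirna, _, sheet, truth = simulate(cfg)
        res = DifferentialExpressionModel.from_sample_sheet(mirna, sheet, "co").fit()
        sig = res.significant
        up = set(sig.loc[sig["direction"] == "up", "feature_id"])
        down = set(sig.loc[sig["direction"] == "down", "feature_id"])
        true_up = {m for m, d in truth.de_mirnas["co"].items() if d > 0}
        true_down = {m for m, d in truth.de_mirnas["co"].items() if d < 0}
        assert abs(len(up & true_up) - 83) <= 0.05 * 83
        assert abs(len(down & true_down) - 122) <= 0.05 * 122
        precision = (len(up & true_up) + len(down & true_down)) / (len(up) + len(down))
        assert precision >= 0.9

    def test_summary_mentions_counts(self, recovery_sim):
        _, (mirna, _, sheet, _) = recovery_sim
        res = DifferentialExpressionModel.from_sample_sheet(mirna, sheet, "co").fit()
        text = res.summary()
        assert "dispersion" in text and "significant" in text
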