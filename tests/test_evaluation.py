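"""ROC/AUC, DeLong and binomial confidence intervals, subgroup metrics."""

import numpy as np
import pytest

from ecindex.evaluation import (
    auc,
    binary_metrics,
    evaluate_scores,
    roc_points,
    subgroup_report,
)
from ecindex.types import SampleMeta, ValidationError


def pairwise_auc_oracle(scores, y):
    """Brute-force mean over all case-control pairs, ties counting 1/2."""
    cases = scores[y == 1]
    controls = scores[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestRoc:
    def test_perfect_ordering_traces_the_corner(self):
        scores = np.array([5.0, 4.0, 1.0, 0.0])
        y = np.array([1, 1, 0, 0])
        assert roc_points(scores, y) == [(0, 0), (0, 0.5), (0, 1), (0.5, 1), (1, 1)]

    def test_constant_scores_give_diagonal(self):
        assert roc_points(np.ones(6), np.array([1, 1, 1, 0, 0, 0])) == [
            (0, 0), (1, 1)]

    def test_six_sample_vector_matches_threshold_enumeration(self):
        scores = np.array([3.0, 2.0, 2.0, 1.0, 0.5, 0.5])
        y = np.array([1, 1, 0, 1, 0, 0])
        points = roc_points(scores, y)
        # exhaustive: at every threshold t, call positive iff score >= t
        expected = {(0.0, 0.0), (1.0, 1.0)}
        for t in np.unique(scores):
            calls = scores >= t
            tpr = np.sum(calls & (y == 1)) / 3
            fpr = np.sum(calls & (y == 0)) / 3
            expected.add((fpr, tpr))
        assert set(points) == expected
        # ordered and monotone
        assert points == sorted(points)

    def test_matches_sklearn_roc_curve(self, rng):
        from sklearn.metrics import roc_curve

        scores = np.round(rng.normal(size=30), 1)  # force ties
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
        ours = roc_points(scores, y)
        assert set(zip(fpr.round(12), tpr.round(12))) <= {
            (round(a, 12), round(b, 12)) for a, b in ours}

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            roc_points(np.ones(3), np.ones(3))


class TestAuc:
    def test_perfect_and_constant(self):
        y = np.array([1, 1, 0, 0])
        assert auc(np.array([2.0, 3.0, 0.0, 1.0]), y).auc == 1.0
        assert auc(np.ones(4), y).auc == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.normal(size=n), 1)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            assert abs(auc(scores, y).auc - pairwise_auc_oracle(scores, y)) < 1e-12

    def test_equals_trapezoid_integration_of_roc(self, rng):
        scores = rng.normal(size=40)  # continuous, tie-free
        y = np.array([1] * 15 + [0] * 25)
        pts = np.array(roc_points(scores, y))
        trapezoid = np.trapezoid(pts[:, 1], pts[:, 0])
        assert abs(auc(scores, y).auc - trapezoid) < 1e-12

    def test_delong_ci_matches_pROC_reference_values(self):
        # 8 cases / 12 controls with a cross-group tie; the expected AUC,
        # DeLong variance and CI were computed with R's pROC (v1.19)
        # and frozen here.
        scores = np.array([
            3.1, 2.4, 2.4, 1.9, 1.7, 0.8, 0.5, -0.2,
            2.4, 1.1, 0.9, 0.4, 0.2, 0.0, -0.3, -0.5, -0.8, -1.1, -1.4, -2.0,
        ])
        y = np.array([1] * 8 + [0] * 12)
        r = auc(scores, y)
        assert abs(r.auc - 0.84375) < 1e-12
        assert abs(r.variance - 0.008046424062049) < 1e-12
        assert abs(r.ci_low - 0.667937580961401) < 1e-9
        assert r.ci_high == 1.0  # clipped at the top of the scale

    def test_degenerate_separation_collapses_ci(self):
        r = auc(np.array([9.0, 8.0, 1.0, 0.0]), np.array([1, 1, 0, 0]))
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)


def wilson_interval_oracle(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval, written out independently."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestBinaryMetrics:
    def test_point_estimates(self):
        calls = np.r_[np.ones(96), np.zeros(4), np.zeros(100)]
        y = np.r_[np.ones(100), np.zeros(100)]
        bm = binary_metrics(calls, y)
        assert bm.sensitivity.value == 0.96
        assert bm.specificity.value == 1.0
        assert bm.accuracy.value == 0.98

    def test_all_correct_has_unit_upper_bound(self):
        y = np.array([1] * 5 + [0] * 5)
        bm = binary_metrics(y, y)
        for m in (bm.sensitivity, bm.specificity, bm.accuracy):
            assert m.value == 1.0
            assert m.ci_high == 1.0

    @pytest.mark.parametrize("k,n", [(90, 100), (3, 17), (0, 9), (45, 45)])
    def test_wilson_matches_closed_form(self, k, n):
        calls = np.r_[np.ones(k), np.zeros(n - k), np.zeros(5)]
        y = np.r_[np.ones(n), np.zeros(5)]
        got = binary_metrics(calls, y).sensitivity
        lo, hi = wilson_interval_oracle(k, n)
        assert abs(got.ci_low - lo) < 1e-9
        assert abs(got.ci_high - hi) < 1e-9

    def test_clopper_pearson_is_wider(self):
        calls = np.r_[np.ones(90), np.zeros(10), np.zeros(20)]
        y = np.r_[np.ones(100), np.zeros(20)]
        w = binary_metrics(calls, y, ci_method="wilson").sensitivity
        cp = binary_metrics(calls, y, ci_method="clopper_pearson").sensitivity
        assert cp.ci_low <= w.ci_low and cp.ci_high >= w.ci_high

    def test_interval_shrinks_with_n(self):
        widths = []
        for n in (20, 80, 320):
            k = int(0.9 * n)
            calls = np.r_[np.ones(k), np.zeros(n - k), np.zeros(10)]
            y = np.r_[np.ones(n), np.zeros(10)]
            m = binary_metrics(calls, y).sensitivity
            assert 0.0 <= m.ci_low <= m.value <= m.ci_high <= 1.0
            widths.append(m.ci_high - m.ci_low)
        assert widths == sorted(widths, reverse=True)


class TestSubgroups:
    def _meta(self):
        stages = ["0", "I", "I", "II", "III", "IV", "IV"]
        sources = ["noncancer1", "noncancer1", "noncancer2", "noncancer3"]
        meta = [SampleMeta(f"c{i}", "case", stage=s) for i, s in enumerate(stages)]
        meta += [SampleMeta(f"n{i}", "control", control_source=s)
                 for i, s in enumerate(sources)]
        y = np.array([1] * len(stages) + [0] * len(sources))
        return meta, y

    def test_stage_sensitivities_and_partition(self, rng):
        meta, y = self._meta()
        scores = np.where(y == 1, 1.0, -1.0) + 0.0
        scores[5] = 2.0  # stage IV case strongly positive
        rep = subgroup_report(scores, y, meta, "stage")
        assert rep["IV"].value == 1.0
        assert sum(m.n for m in rep.values()) == int(y.sum())
        # pooled by stratum sizes reproduces the overall sensitivity
        overall = binary_metrics((scores > 0).astype(int), y).sensitivity.value
        pooled = sum(m.value * m.n for m in rep.values()) / int(y.sum())
        assert abs(pooled - overall) < 1e-12

    def test_control_source_specificities(self):
        meta, y = self._meta()
        scores = np.where(y == 1, 1.0, -1.0) + 0.0
        scores[-1] = 0.5  # one noncancer3 control falsely positive
        rep = subgroup_report(scores, y, meta, "control_source")
        assert rep["noncancer1"].value == 1.0
        assert rep["noncancer3"].value == 0.0
        assert sum(m.n for m in rep.values()) == int((y == 0).sum())

    def test_full_report_assembles(self):
        meta, y = self._meta()
        scores = np.where(y == 1, 1.0, -1.0) + 0.0
        rep = evaluate_scores(scores, y, meta=meta)
        assert rep.n_case == 7 and rep.n_control == 4
        assert rep.auc.auc == 1.0
        assert set(rep.by_stage) == {"0", "I", "II", "III", "IV"}
        assert set(rep.by_control_source) == {"noncancer1", "noncancer2", "noncancer3"}

    def test_stage_dependent_effects_order_sensitivities(self):
        # planted effect grows with stage; stage sensitivity must follow
        from ecindex.synthetic import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_case=150, n_control=50, n_mirna=10, n_differential=1,
            effect_size=2.0, detection_dropout=0.0,
            stage_distribution={"0": 0.34, "II": 0.33, "IV": 0.33},
            effect_by_stage={"0": 0.1, "II": 1.0, "IV": 3.0},
            seed=5,
        )
        study, truth = simulate_cohort(cfg)
        j = study.mirna_ids.index(truth.differential_mirna_ids[0])
        sign = np.sign(truth.effects[truth.differential_mirna_ids[0]])
        scores = sign * np.log2(study.signal[:, j])
        y = study.group_labels
        cut = np.median(scores[y == 0])
        rep = subgroup_report(scores - cut, y, study.samples, "stage")
        assert rep["0"].value <= rep["II"].value <= rep["IV"].value
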