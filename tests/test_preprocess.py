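"""Positive-call selection, internal-control normalization, robust filter."""

import numpy as np
import pytest

from ecindex.preprocess import (
    NormalizationConfig,
    RobustFilterConfig,
    control_means,
    freeze_reference,
    normalize_internal_controls,
    positive_call_subtract,
    read_normalization_config,
    robust_filter,
    write_normalization_config,
)
from ecindex.types import NormalizedMatrix, RawExpressionStudy, SampleMeta, ValidationError


def _study(signal, background, groups=None):
    signal = np.asarray(signal, dtype=float)
    n, m = signal.shape
    groups = groups or ["case"] * (n // 2) + ["control"] * (n - n // 2)
    samples = [SampleMeta(f"s{i}", groups[i]) for i in range(n)]
    return RawExpressionStudy(
        mirna_ids=[f"miR-{j}" for j in range(m)],
        samples=samples,
        signal=signal,
        background=np.asarray(background, dtype=float),
    )


def _matrix(linear, mirna_ids=None):
    linear = np.asarray(linear, dtype=float)
    n, m = linear.shape
    with np.errstate(invalid="ignore"):
        values = np.log2(np.maximum(linear, 0.1))
    return NormalizedMatrix(
        mirna_ids=mirna_ids or [f"miR-{j}" for j in range(m)],
        sample_ids=[f"s{i}" for i in range(n)],
        values=values,
        linear_values=linear,
    )


class TestPositiveCallSubtract:
    def test_hand_computed_toy_matrix(self):
        # backgrounds 30 and 25; calls strictly above background survive
        study = _study(
            [[100.0, 20.0, 30.0], [250.0, 25.0, 26.0]],
            [30.0, 25.0],
        )
        out = positive_call_subtract(study)
        expected = np.array([[70.0, np.nan, np.nan], [225.0, np.nan, 1.0]])
        np.testing.assert_allclose(out.linear_values, expected)
        # log layer mirrors the same missingness
        assert np.array_equal(np.isnan(out.values), np.isnan(expected))
        np.testing.assert_allclose(out.values[0, 0], np.log2(70.0))

    def test_never_negative_and_signal_at_background_is_missing(self, rng):
        signal = rng.uniform(0, 200, size=(10, 30))
        signal[0, 0] = 50.0  # exactly at background -> negative call
        study = _study(signal, np.full(10, 50.0))
        out = positive_call_subtract(study)
        present = ~np.isnan(out.linear_values)
        assert np.all(out.linear_values[present] > 0)
        assert np.isnan(out.linear_values[0, 0])


class TestNormalization:
    def _control_study(self, control_levels, extra=None):
        """One sample per requested control mean; 3 internal controls set
        to that mean plus one free miRNA column."""
        rows = []
        for level, other in zip(control_levels, extra or [1000.0] * len(control_levels)):
            rows.append([level, level, level, other])
        return _matrix(
            rows, mirna_ids=["miR-149-3p", "miR-2861", "miR-4463", "miR-x"])

    def test_three_array_fixture_matches_hand_computation(self):
        # control means {200, 400, 800} -> R = 466.67, factors R/c_i
        m = self._control_study([200.0, 400.0, 800.0])
        out = normalize_internal_controls(m)
        R = (200 + 400 + 800) / 3
        np.testing.assert_allclose(R, 466.6666666666667)
        cfg = NormalizationConfig()
        np.testing.assert_allclose(control_means(out, cfg), [R, R, R], rtol=1e-12)
        np.testing.assert_allclose(
            out.linear_values[:, 3], [1000 * R / 200, 1000 * R / 400, 1000 * R / 800],
            rtol=1e-12)

    def test_halving_example_and_single_array_identity(self):
        m = self._control_study([1000.0])
        out = normalize_internal_controls(
            m, NormalizationConfig(reference_level="fixed_value", fixed_reference=500.0))
        np.testing.assert_allclose(out.linear_values, m.linear_values / 2, rtol=1e-12)
        # single array under grand mean: R = c_1, identity
        out2 = normalize_internal_controls(m)
        np.testing.assert_allclose(out2.linear_values, m.linear_values, rtol=1e-12)

    def test_fixed_reference_removes_array_scaling_exactly(self, rng):
        linear = rng.uniform(10, 5000, size=(4, 6))
        ids = ["miR-149-3p", "miR-2861", "miR-4463", "a", "b", "c"]
        cfg = NormalizationConfig(reference_level="fixed_value", fixed_reference=700.0)
        base = normalize_internal_controls(_matrix(linear, ids), cfg)
        for k in (0.1, 3.0, 250.0):
            scaled = linear.copy()
            scaled[2] *= k
            out = normalize_internal_controls(_matrix(scaled, ids), cfg)
            np.testing.assert_allclose(out.linear_values, base.linear_values,
                                       rtol=1e-10)
            np.testing.assert_allclose(out.values, base.values, rtol=1e-10)

    def test_grand_mean_scaling_changes_only_global_level(self, rng):
        # scaling one array rescales R, hence all arrays, by a common ratio
        linear = rng.uniform(10, 5000, size=(4, 6))
        ids = ["miR-149-3p", "miR-2861", "miR-4463", "a", "b", "c"]
        base = normalize_internal_controls(_matrix(linear, ids))
        scaled = linear.copy()
        scaled[2] *= 7.0
        out = normalize_internal_controls(_matrix(scaled, ids))
        ratio = out.linear_values / base.linear_values
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-10)

    def test_log_floor_applied(self):
        m = self._control_study([100.0], extra=[0.01])
        out = normalize_internal_controls(
            m, NormalizationConfig(reference_level="fixed_value", fixed_reference=100.0))
        assert out.values[0, 3] == np.log2(0.1)

    def test_missing_control_config_error(self):
        m = _matrix([[100.0, 100.0]], mirna_ids=["miR-149-3p", "miR-x"])
        with pytest.raises(ValidationError, match="miR-2861"):
            normalize_internal_controls(m)

    def test_array_with_no_detected_controls_error(self):
        linear = np.array([[100.0, 100.0, 100.0, 5.0],
                           [np.nan, np.nan, np.nan, 5.0]])
        m = _matrix(linear, ["miR-149-3p", "miR-2861", "miR-4463", "miR-x"])
        with pytest.raises(ValidationError, match="s1"):
            normalize_internal_controls(m)

    def test_freeze_reference_round_trips(self, tmp_path):
        m = self._control_study([200.0, 400.0, 800.0])
        frozen = freeze_reference(m)
        assert frozen.reference_level == "fixed_value"
        np.testing.assert_allclose(frozen.fixed_reference, (200 + 400 + 800) / 3)
        write_normalization_config(frozen, tmp_path / "norm.json")
        assert read_normalization_config(tmp_path / "norm.json") == frozen


class TestRobustFilter:
    def test_selected_and_strictness(self):
        # miR-0: 100 everywhere -> selected. miR-1: above threshold in
        # exactly half of the case group -> NOT selected ("more than 50%").
        # miR-2: exactly 64 -> NOT selected (strictly "exceeding 64").
        linear = np.array([
            [100.0, 100.0, 64.0],
            [100.0, 100.0, 64.0],
            [100.0, 10.0, 64.0],
            [100.0, 10.0, 64.0],
            [100.0, 100.0, 64.0],
            [100.0, 100.0, 64.0],
        ])
        groups = np.array([1, 1, 1, 1, 0, 0])
        assert robust_filter(_matrix(linear), groups) == ["miR-0"]

    def test_missing_counts_as_below_threshold(self):
        linear = np.array([[1000.0], [np.nan], [1000.0], [np.nan]])
        groups = np.array([1, 1, 0, 0])
        assert robust_filter(_matrix(linear), groups) == []

    def test_matches_brute_force_count(self, rng):
        for _ in range(25):
            n, m = int(rng.integers(4, 12)), 20
            linear = rng.uniform(0, 200, size=(n, m))
            linear[rng.random(size=(n, m)) < 0.2] = np.nan
            groups = rng.integers(0, 2, size=n)
            if len(set(groups)) < 2:
                continue
            cfg = RobustFilterConfig(
                signal_threshold=float(rng.uniform(20, 120)),
                sample_fraction=float(rng.uniform(0.2, 0.9)),
            )
            mat = _matrix(linear)
            got = robust_filter(mat, groups, cfg)
            expected = []
            for j in range(m):
                ok = True
                for g in (0, 1):
                    idx = [i for i in range(n) if groups[i] == g]
                    count = sum(
                        1 for i in idx
                        if not np.isnan(linear[i, j]) and linear[i, j] > cfg.signal_threshold
                    )
                    if not count > cfg.sample_fraction * len(idx):
                        ok = False
                if ok:
                    expected.append(f"miR-{j}")
            assert got == expected

    def test_monotone_in_threshold_and_fraction(self, rng):
        linear = rng.uniform(0, 200, size=(12, 30))
        groups = np.array([1] * 6 + [0] * 6)
        mat = _matrix(linear)
        prev = None
        for thr in (10, 40, 70, 100, 150):
            sel = set(robust_filter(mat, groups, RobustFilterConfig(signal_threshold=thr)))
            if prev is not None:
                assert sel <= prev
            prev = sel
        prev = None
        for frac in (0.2, 0.4, 0.6, 0.8):
            sel = set(robust_filter(mat, groups,
                                    RobustFilterConfig(sample_fraction=frac)))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_any_group_rule_is_weaker(self, rng):
        linear = rng.uniform(0, 200, size=(10, 25))
        groups = np.array([1] * 5 + [0] * 5)
        mat = _matrix(linear)
        strict = set(robust_filter(mat, groups, RobustFilterConfig()))
        weak = set(robust_filter(mat, groups,
                                 RobustFilterConfig(group_rule="any_group")))
        assert strict <= weak

    def test_errors(self):
        mat = _matrix(np.full((4, 2), 100.0))
        with pytest.raises(ValidationError, match="two groups"):
            robust_filter(mat, np.array([1, 1, 1, 1]))
        with pytest.raises(ValidationError):
            RobustFilterConfig(signal_threshold=0.0)
        with pytest.raises(ValidationError):
            RobustFilterConfig(sample_fraction=1.5)
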