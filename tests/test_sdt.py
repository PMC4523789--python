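"""Unit and property tests for the SDT response model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr, ndtri

from quicksdt.sdt import (
    DualCriterion,
    LapseConfig,
    SensitivityParams,
    apply_lapse,
    cued_probabilities,
    dprime,
    interval2_probability,
    rated_probabilities,
    yes_probability,
)

REF = SensitivityParams(tau=0.10, gamma=2.0, beta=5.0)

sens_strategy = st.builds(
    SensitivityParams,
    tau=st.floats(0.005, 0.9),
    gamma=st.floats(0.4, 10.0),
    beta=st.floats(2.0, 8.0),
)


class TestDprime:
    @pytest.mark.parametrize(
        "c, expected",
        [
            (0.10, 1.0),  # threshold definition: d'(tau) = 1
            (0.0, 0.0),
            (0.99, 5 * 98.01 / np.sqrt(24 + 98.01**2)),  # = 4.9938
        ],
    )
    def test_reference_values(self, c, expected):
        assert dprime(c, REF) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [-0.1, np.nan, np.inf])
    def test_invalid_contrast_rejected(self, bad):
        with pytest.raises(ValueError):
            dprime(bad, REF)

    @settings(derandomize=True, max_examples=60)
    @given(sens=sens_strategy)
    def test_threshold_identity_and_saturation(self, sens):
        """d'(tau) = 1 exactly, and d' stays strictly below beta."""
        assert dprime(sens.tau, sens) == pytest.approx(1.0, abs=1e-12)
        c = np.geomspace(1e-4, 0.999, 50)
        d = dprime(c, sens)
        assert np.all(np.diff(d) >= -1e-12)  # monotone non-decreasing
        assert np.all(d < sens.beta)

    def test_invalid_params_rejected(self):
        for kwargs in ({"tau": 0.0}, {"tau": 1.5}, {"gamma": -1.0}, {"beta": 0.9}):
            with pytest.raises(ValueError):
                SensitivityParams(**{"tau": 0.1, "gamma": 2.0, "beta": 5.0, **kwargs})


class TestYesProbability:
    def test_false_alarm_rate_at_reference_criterion(self):
        # criterion 1.28 corresponds to a 10% false-alarm rate
        assert yes_probability(0.0, REF, 1.28) == pytest.approx(0.1003, abs=2e-4)

    def test_neutral_criterion_null(self):
        assert yes_probability(0.0, REF, 0.0) == pytest.approx(0.5)

    def test_at_threshold(self):
        assert yes_probability(REF.tau, REF, 1.28) == pytest.approx(ndtr(-0.28), abs=1e-9)

    def test_z_transform_recovers_dprime(self):
        """z(P_yes(c)) - z(P_yes(0)) = d'(c) for lapse-free simple detection."""
        lam = 1.1
        for c in (0.03, 0.1, 0.25):
            z_diff = ndtri(yes_probability(c, REF, lam)) - ndtri(
                yes_probability(0.0, REF, lam)
            )
            assert z_diff == pytest.approx(dprime(c, REF), abs=1e-9)


class TestCuedAndRated:
    DEC = DualCriterion(lam_strict=1.96, delta_lam=0.68)

    def test_null_false_alarm_pair(self):
        # strict FA ~ 2.5%, lax FA ~ 10%
        assert cued_probabilities(0.0, "strict", REF, self.DEC) == pytest.approx(
            0.025, abs=1e-3
        )
        assert cued_probabilities(0.0, "lax", REF, self.DEC) == pytest.approx(
            0.10, abs=1e-2
        )

    def test_at_threshold_values(self):
        assert cued_probabilities(REF.tau, "strict", REF, self.DEC) == pytest.approx(
            0.1685, abs=1e-3
        )
        assert cued_probabilities(REF.tau, "lax", REF, self.DEC) == pytest.approx(
            0.3890, abs=1e-3
        )

    def test_zero_delta_collapses_states(self):
        dec = DualCriterion(1.5, 0.0)
        c = np.geomspace(0.01, 0.9, 20)
        lax = cued_probabilities(c, "lax", REF, dec)
        strict = cued_probabilities(c, "strict", REF, dec)
        assert np.allclose(lax, strict)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            DualCriterion(1.5, -0.1)

    def test_lax_dominates_strict(self):
        c = np.geomspace(0.005, 0.95, 40)
        assert np.all(
            cued_probabilities(c, "lax", REF, self.DEC)
            >= cued_probabilities(c, "strict", REF, self.DEC)
        )

    def test_rated_null_distribution(self):
        # null Yes/No rates of the conservative rated state: (2.5%, 90%)
        dec = DualCriterion(float(ndtri(0.975)), float(ndtri(0.975)) - float(ndtri(0.90)))
        p_yes, p_ns, p_no = rated_probabilities(0.0, REF, dec)
        assert p_yes == pytest.approx(0.025, abs=1e-9)
        assert p_no == pytest.approx(0.900, abs=1e-9)
        assert p_ns == pytest.approx(0.075, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        sens=sens_strategy,
        lam_strict=st.floats(-0.5, 3.0),
        delta=st.floats(0.0, 2.5),
        c=st.floats(0.0, 0.99),
    )
    def test_rated_partitions_and_collapses_to_cued(self, sens, lam_strict, delta, c):
        """Rated probabilities sum to 1; Yes+NotSure equals the cued lax curve."""
        dec = DualCriterion(lam_strict, delta)
        p_yes, p_ns, p_no = rated_probabilities(c, sens, dec)
        assert p_yes + p_ns + p_no == pytest.approx(1.0, abs=1e-12)
        assert p_yes + p_ns == pytest.approx(
            cued_probabilities(c, "lax", sens, dec), abs=1e-12
        )

    def test_rated_monotonicity(self):
        c = np.geomspace(0.005, 0.95, 40)
        p_yes, _, p_no = rated_probabilities(c, REF, self.DEC)
        assert np.all(np.diff(p_yes) >= -1e-12)
        assert np.all(np.diff(p_no) <= 1e-12)


class TestForcedChoice:
    def test_neutral_null_is_half(self):
        assert interval2_probability(0.0, 0.0, REF, 0.0) == pytest.approx(0.5)

    def test_threshold_percent_correct(self):
        # signal at d' = 1 with a neutral criterion: ~76% correct
        assert interval2_probability(0.0, REF.tau, REF, 0.0) == pytest.approx(
            0.7602, abs=1e-3
        )

    def test_interval_bias_null_rate(self):
        # lam_fc = ndtri(0.30) makes the observer respond Interval 2 at 70%
        assert interval2_probability(0.0, 0.0, REF, float(ndtri(0.30))) == pytest.approx(
            0.70, abs=1e-9
        )

    @settings(derandomize=True, max_examples=50)
    @given(sens=sens_strategy, c1=st.floats(0.0, 0.9), c2=st.floats(0.0, 0.9))
    def test_antisymmetry_under_interval_swap(self, sens, c1, c2):
        p = interval2_probability(c1, c2, sens, 0.0)
        q = interval2_probability(c2, c1, sens, 0.0)
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestLapse:
    def test_upper_asymptote_99_percent(self):
        out = apply_lapse([1.0, 0.0], LapseConfig(0.02, 2))
        assert np.allclose(out, [0.99, 0.01])

    def test_zero_lapse_is_identity(self):
        p = np.array([0.3, 0.7])
        assert np.allclose(apply_lapse(p, LapseConfig(0.0, 2)), p)

    def test_three_alternative_split(self):
        out = apply_lapse([1.0, 0.0, 0.0], LapseConfig(0.02, 3))
        assert np.allclose(out, [0.98 + 0.02 / 3, 0.02 / 3, 0.02 / 3])

    def test_non_distribution_rejected(self):
        with pytest.raises(ValueError):
            apply_lapse([0.5, 0.2], LapseConfig(0.02, 2))

    @settings(derandomize=True, max_examples=40)
    @given(p=st.floats(0.0, 1.0), eps=st.floats(0.0, 0.099))
    def test_output_bounds(self, p, eps):
        out = apply_lapse([p, 1.0 - p], LapseConfig(eps, 2))
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= eps / 2 - 1e-12)
        assert np.all(out <= 1.0 - eps / 2 + 1e-12)
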