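"""Activation dynamics, evidence, and threshold-crossing RT prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tectonic.model import (
    DEFAULT_CONSTANTS,
    MaxCyclesExceeded,
    ModelConstants,
    SlopeSet,
    StartParams,
    act_distractor,
    act_nontarget,
    act_target,
    distractor_slope,
    evidence,
    predict_rt,
    predict_rt_scan,
    target_slope,
)

LN7 = np.log(7.0)


@pytest.mark.parametrize(
    "slope,t,expected,tol",
    [
        (0.004, 0.0, 0.5**10, 1e-12),        # logistic(0) = 1/2
        (0.023, 0.0, 0.5**10, 1e-12),
        (0.01, 500.0, 0.93505, 5e-6),        # direct evaluation
        (0.023, 4000.0, 1.0, 1e-9),          # asymptote
    ],
)
def test_target_activation_values(slope, t, expected, tol):
    assert act_target(slope, t) == pytest.approx(expected, abs=tol)


def test_activation_mirrors_and_bounds():
    # below the float64 saturation point of the logistic
    t = np.linspace(0, 2000, 200)
    a = act_target(0.01, t)
    assert np.all(np.diff(a) > 0) and np.all((a > 0) & (a < 1))
    assert np.allclose(act_nontarget(0.01, t), -a)
    assert np.allclose(act_distractor(0.01, t), -3 * a)
    assert act_nontarget(0.01, 500) == pytest.approx(-0.93505, abs=5e-6)
    assert act_distractor(0.01, 500) == pytest.approx(-2.80514, abs=2e-5)


def test_activation_rejects_non_finite():
    with pytest.raises(ValueError):
        act_target(np.nan, 10.0)
    with pytest.raises(ValueError):
        act_target(0.01, np.inf)


def test_evidence_at_zero_is_slope_free():
    # (1/2)^10 excitation against three inhibitory copies of itself
    expected = np.log((6 + 0.5**10) / (6 - 5 * 0.5**10))
    for slopes in [SlopeSet(0.01, 0.02, 0.005, 0.015), SlopeSet(0.0228, 1e-4, 0.01, 0.02)]:
        for presented in (1, 2, 3):
            assert float(evidence(slopes, presented, 0.0)) == pytest.approx(
                expected, abs=1e-12
            )
    assert expected == pytest.approx(0.000977, abs=1e-6)


def test_evidence_example_and_supremum():
    s = SlopeSet(0.01, 0.01, 0.01, 0.01)
    assert float(evidence(s, 1, 500.0)) == pytest.approx(
        np.log(6.93505 / 1.32475), abs=1e-4
    )
    assert float(evidence(s, 1, 1e7)) == pytest.approx(LN7, abs=1e-9)


@given(
    st.lists(
        st.floats(min_value=1e-4, max_value=0.0229), min_size=4, max_size=4
    ),
    st.sampled_from([1, 2, 3]),
)
@settings(max_examples=50, deadline=None)
def test_evidence_strictly_increasing_and_bounded(slopes, presented):
    s = SlopeSet(*slopes)
    t = np.linspace(0.0, 5000.0, 400)
    ev = evidence(s, presented, t)
    assert np.all(np.diff(ev) >= 0)
    assert np.all((ev > 0) & (ev <= LN7))
    # strictly increasing before the float64 saturation of the activations
    strict = t * max(slopes) < 25
    if strict.sum() > 2:
        assert np.all(np.diff(ev[strict]) > 0)


def test_predict_rt_threshold_already_met():
    fast = ModelConstants(threshold_beta=0.0009)
    assert predict_rt(SlopeSet(0.01, 0.01, 0.01, 0.01), 1, fast) == 0.0


def test_predict_rt_degenerate_slopes_never_cross():
    with pytest.raises(MaxCyclesExceeded):
        predict_rt(SlopeSet(0.0, 0.0, 0.0, 0.0), 1)
    with pytest.raises(MaxCyclesExceeded):
        predict_rt_scan(SlopeSet(0.0, 0.0, 0.0, 0.0), 1)


def test_predict_rt_matches_integer_scan(rng):
    for _ in range(200):
        s = SlopeSet(*rng.uniform(2e-3, 0.022, 4))
        rt = predict_rt(s, int(rng.integers(1, 4)))
        scan = predict_rt_scan(s, 1)
        rt1 = predict_rt(s, 1)
        assert abs(rt1 - scan) <= 1.0
        assert 0 <= rt <= DEFAULT_CONSTANTS.max_cycles


def test_predict_rt_monotone_in_distractor_slope():
    base = np.linspace(2e-3, 0.02, 12)
    rts = [predict_rt(SlopeSet(0.008, 0.008, 0.008, sd), 1) for sd in base]
    assert np.all(np.diff(rts) < 0)  # more inhibition -> faster decision


@pytest.mark.parametrize(
    "tstart,tswell,x,expected",
    [
        (0.0, 1.7, 0.0, 0.0115),
        (50.0, 0.0, 0.0, 0.023),
        (1.0, 2.0, 0.5, 0.020258),
    ],
)
def test_slope_equations(tstart, tswell, x, expected):
    assert target_slope(tstart, tswell, x) == pytest.approx(expected, abs=5e-6)
    assert distractor_slope(tstart, tswell, x) == pytest.approx(expected, abs=5e-6)


def test_shared_slope_per_target_by_construction():
    # perceived and remembered activation of the same target use one slope
    p = StartParams((-0.5, 0.0, 0.5), -0.2, -1.0, -0.3)
    s = p.slopes(0.7)
    assert act_nontarget(s.slope_t2, 300.0) == -act_target(s.slope_t2, 300.0)
    assert s.targets.shape == (3,)


def test_constants_invariants_enforced():
    with pytest.raises(ValueError):
        ModelConstants(evidence_constant=4.9)  # denominator can reach zero
    with pytest.raises(ValueError):
        ModelConstants(threshold_beta=2.0)  # above the ln 7 supremum
    ModelConstants()  # defaults valid
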