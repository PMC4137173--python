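"""Two-stage estimation: objective, noise handling, links, and backfit."""

import numpy as np
import pytest
from scipy import stats

from tectonic import fitting
from tectonic.design import CONDITIONS
from tectonic.fitting import (
    FREE_PARAM_COUNTS,
    ModelSpec,
    apply_link,
    assign_noise,
    backfit_rts,
    fit_link,
    objective,
    sample_noise,
    trial_evidence,
)
from tectonic.model import StartParams, evidence, predict_rt_scan


PARAMS = StartParams((-0.1, -0.05, -0.15), -0.2, -1.2, -0.35)


def test_model_spec_validation_and_counts():
    assert ModelSpec("rp", "rp_noise").n_free_params == 7
    assert FREE_PARAM_COUNTS == {
        "inhibition_only": 9, "excitation_only": 15, "rp": 7, "pn": 9,
    }
    with pytest.raises(ValueError):
        ModelSpec("bogus", "gaussian")
    with pytest.raises(ValueError):
        ModelSpec("rp", "bogus")


def test_objective_zero_at_self_consistent_rts(rng):
    x = rng.standard_normal(40)
    presented = rng.integers(1, 4, 40)
    rt = backfit_rts(PARAMS, presented, x)
    assert objective(PARAMS, rt, presented, x) < 1e-12


def test_objective_matches_brute_force(rng):
    x = rng.standard_normal(10)
    presented = rng.integers(1, 4, 10)
    rt = rng.uniform(300, 900, 10)
    total = 0.0
    for h in range(10):
        s = PARAMS.slopes(x[h])
        total += (1.0 - float(evidence(s, int(presented[h]), rt[h]))) ** 2
    assert objective(PARAMS, rt, presented, x) == pytest.approx(total, rel=1e-12)


def test_objective_single_trial_residual():
    # a trial whose evidence at its observed RT is 0.9 contributes 0.01
    from scipy.optimize import brentq

    x = np.array([0.0])
    presented = np.array([1])

    def ev_at(t):
        return float(
            trial_evidence(PARAMS, presented, x, np.array([t]))[0]
        ) - 0.9

    rt = np.array([brentq(ev_at, 1.0, 5000.0, xtol=1e-10)])
    assert objective(PARAMS, rt, presented, x) == pytest.approx(0.01, abs=1e-9)


def test_objective_invariant_to_trial_order(rng):
    x = rng.standard_normal(25)
    presented = rng.integers(1, 4, 25)
    rt = rng.uniform(300, 900, 25)
    perm = rng.permutation(25)
    assert objective(PARAMS, rt, presented, x) == pytest.approx(
        objective(PARAMS, rt[perm], presented[perm], x[perm]), rel=1e-12
    )


def test_assign_noise_rank_pairing():
    x = assign_noise(np.array([-1.0, 0.0, 1.0]), np.array([500.0, 400.0, 600.0]))
    assert np.allclose(x, [0.0, -1.0, 1.0])
    # ties keep original trial order (stable)
    x = assign_noise(np.array([3.0, 1.0, 2.0]), np.array([500.0, 500.0, 500.0]))
    assert np.allclose(x, [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        assign_noise(np.zeros(3), np.zeros(4))


def test_sample_noise_sources():
    a = sample_noise("gaussian", 100, 5)
    assert np.allclose(a, sample_noise("gaussian", 100, 5))  # reproducible
    big = sample_noise("gaussian", 100_000, 5)
    assert abs(big.mean()) < 0.02 and abs(big.std() - 1) < 0.02
    r = sample_noise("rectangular", 100_000, 5)
    half = np.sqrt(3.0)
    assert r.min() >= -half and r.max() <= half
    assert abs(r.mean()) < 0.02 and abs(r.std() - 1) < 0.02


def test_sample_noise_rp_thinning(rng):
    pool = rng.normal(0, 1, 200)
    out = sample_noise("rp_noise", 150, 1, pool)
    assert np.allclose(out, sample_noise("rp_noise", 150, 99, pool))
    assert out.min() == pool.min() and out.max() == pool.max()
    assert np.all(np.diff(out) >= 0) and len(np.unique(out)) == 150
    small = sample_noise("rp_noise", 150, 1, pool[:100])  # pool smaller: repeats
    assert len(small) == 150 and len(np.unique(small)) == 100
    with pytest.raises(ValueError):
        sample_noise("rp_noise", 10, 1, None)


def test_fit_link_cases(rng):
    link = fit_link(np.array([2.0, 4.0, 6.0, 8.0]), np.array([1.0, 2.0, 3.0, 4.0]), "dstart")
    assert link.intercept == pytest.approx(0.0, abs=1e-12)
    assert link.coefficient == pytest.approx(2.0)
    flat = fit_link(np.full(4, 3.5), np.array([1.0, 2.0, 3.0, 4.0]), "dstart")
    assert flat.coefficient == pytest.approx(0.0, abs=1e-12)
    assert flat.intercept == pytest.approx(3.5)
    const_pred = fit_link(np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 2.0), "dstart")
    assert const_pred.coefficient == 0.0 and const_pred.intercept == pytest.approx(2.5)
    y, a = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
    ours = fit_link(y, a, "dstart")
    ref = stats.linregress(a, y)
    assert ours.coefficient == pytest.approx(ref.slope, rel=1e-9)
    assert ours.intercept == pytest.approx(ref.intercept, rel=1e-9)


def test_apply_link_and_collinear_roundtrip():
    link = fit_link(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0.5, 1.0, 1.5, 2.0]), "dstart")
    for amp, y in zip([0.5, 1.0, 1.5, 2.0], [1.0, 2.0, 3.0, 4.0]):
        assert apply_link(link, amp) == pytest.approx(y, abs=1e-10)


def test_backfit_roundtrip_and_threshold_property(rng):
    x = rng.standard_normal(200)
    presented = rng.integers(1, 4, 200)
    rt = backfit_rts(PARAMS, presented, x)
    again = backfit_rts(PARAMS, presented, x)
    assert np.allclose(rt, again)
    ev = trial_evidence(PARAMS, presented, x, rt)
    assert np.all(np.abs(ev - 1.0) < 1e-6)
    # continuous solver agrees with the paper-style integer scan
    for h in range(0, 200, 20):
        scan = predict_rt_scan(PARAMS.slopes(x[h]), int(presented[h]))
        assert abs(rt[h] - scan) <= 1.0


def test_zero_swell_makes_noise_irrelevant(rng):
    flat = StartParams((-0.1, -0.05, -0.15), 0.0, -1.2, 0.0)
    presented = rng.integers(1, 4, 50)
    rt_g = backfit_rts(flat, presented, rng.standard_normal(50))
    rt_r = backfit_rts(flat, presented, sample_noise("rectangular", 50, 3))
    assert np.allclose(rt_g, rt_r)


def test_objective_near_zero_at_truth_with_matched_noise(small_dataset):
    trials, amps, truth = small_dataset
    t1 = trials[trials["participant_id"] == 1]
    for cond in CONDITIONS:
        sub = fitting._condition_trials(t1, cond)
        obj = objective(
            truth.params[1][cond],
            sub["rt_ms"].to_numpy(),
            sub["stimulus_level"].to_numpy(int),
            sub["x"].to_numpy(),
        )
        assert obj < 1e-12


def test_fit_participant_deterministic(small_dataset):
    trials, amps, _ = small_dataset
    t1 = trials[trials["participant_id"] == 1]
    a1 = amps[amps["participant_id"] == 1]
    spec = ModelSpec("inhibition_only", "rp_noise")
    f1 = fitting.fit_participant(t1, spec, 77, a1)
    f2 = fitting.fit_participant(t1, spec, 77, a1)
    for cond in CONDITIONS:
        assert f1.params[cond] == f2.params[cond]
        assert f1.objectives[cond] == f2.objectives[cond]
        assert np.array_equal(f1.noise[cond][1], f2.noise[cond][1])


def test_fit_requires_amplitudes_for_eeg_variants(small_dataset):
    trials, _, _ = small_dataset
    t1 = trials[trials["participant_id"] == 1]
    with pytest.raises(ValueError):
        fitting.fit_participant(t1, ModelSpec("rp", "gaussian"), 1, None)
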