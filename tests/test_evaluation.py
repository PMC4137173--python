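"""Vincentized distributions, densities, chi-square, and moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tectonic.evaluation import (
    CHI_SQUARE_DF,
    chi_square_gof,
    density,
    group_distribution,
    moment_difference_table,
    moments,
    vincentize,
)


def brute_vincentize(rts, q=20):
    rts = np.sort(np.asarray(rts, dtype=float))
    base, rem = divmod(len(rts), q)
    out, i = [], 0
    for b in range(q):
        size = base + (1 if b < rem else 0)
        out.append(rts[i:i + size].mean())
        i += size
    return np.array(out)


def test_vincentize_exact_cases():
    vals = np.arange(20.0)[::-1]
    assert np.allclose(vincentize(vals), np.sort(vals))
    assert np.allclose(vincentize(np.arange(1.0, 41.0)), np.arange(1.5, 40, 2.0))
    with pytest.raises(ValueError):
        vincentize(np.arange(19.0))


def test_vincentize_remainder_matches_brute_force(rng):
    for n in (47, 63, 100, 141):
        vals = rng.uniform(300, 900, n)
        assert np.allclose(vincentize(vals), brute_vincentize(vals))


def test_vincentize_preserves_grand_mean(rng):
    vals = rng.uniform(300, 900, 147)
    q = vincentize(vals)
    base, rem = divmod(147, 20)
    sizes = np.full(20, base)
    sizes[:rem] += 1
    assert np.average(q, weights=sizes) == pytest.approx(vals.mean(), rel=1e-12)


def test_group_distribution(rng):
    one = rng.uniform(300, 900, 20)
    assert np.allclose(group_distribution(one), one)
    assert np.allclose(group_distribution(np.vstack([one, one])), one)
    many = rng.uniform(300, 900, (5, 20))
    assert np.allclose(group_distribution(many), many.mean(axis=0))


def test_density_cases(rng):
    q = 500 + 10 * np.arange(20.0)
    assert np.allclose(density(q), 5.0)
    assert np.allclose(density(500 + 50 * np.arange(20.0)), 1.0)
    spacing = rng.uniform(1, 40, 19)
    q = 400 + np.concatenate([[0.0], np.cumsum(spacing)])
    assert np.allclose(density(q), 50.0 / spacing)
    spacing[4] = 0.0  # tied quantiles: infinite density flagged
    tied = 400 + np.concatenate([[0.0], np.cumsum(spacing)])
    assert np.isinf(density(tied)[4])
    with pytest.raises(ValueError):
        density(q[::-1])


def test_chi_square_zero_iff_identical(rng):
    q = np.sort(rng.uniform(400, 900, 20))
    stat, df = chi_square_gof(q, q)
    assert stat == 0.0 and df == CHI_SQUARE_DF
    q2 = q + rng.uniform(0.1, 3.0, 20)
    stat2, _ = chi_square_gof(q, np.sort(q2))
    assert stat2 > 0


def test_chi_square_single_cell_and_oracle(rng):
    q_pred = 500.0 + 10 * np.arange(20.0)
    q_obs = q_pred.copy()
    q_obs[10:] += 2.0  # one spacing changed: density cell 10
    p_obs, p_pred = 50.0 / 12.0, 5.0
    stat, _ = chi_square_gof(q_obs, q_pred)
    assert stat == pytest.approx((p_obs - p_pred) ** 2 / p_pred, rel=1e-12)
    a = np.sort(rng.uniform(400, 900, 20))
    b = np.sort(rng.uniform(400, 900, 20))
    pa, pb = density(a), density(b)
    assert chi_square_gof(a, b)[0] == pytest.approx(
        float(np.sum((pa - pb) ** 2 / pb)), rel=1e-12
    )


def test_moments_exact_and_against_scipy(rng):
    m = moments([1.0, 2.0, 3.0])
    assert m.mean == 2.0
    assert m.dispersion == pytest.approx(np.sqrt(2.0 / 3.0))
    assert m.skewness == pytest.approx(0.0, abs=1e-12)
    assert m.kurtosis == pytest.approx(-1.5)
    sym = np.concatenate([rng.normal(0, 1, 500), -rng.normal(0, 1, 500)[::-1]])
    sym = np.concatenate([sym, -sym])  # exactly symmetric sample
    assert moments(sym).skewness == pytest.approx(0.0, abs=1e-10)
    big = rng.standard_normal(100_000)
    mb = moments(big)
    assert abs(mb.skewness) < 0.05 and abs(mb.kurtosis) < 0.05
    # population-denominator formulas match the scipy conventions
    vals = rng.gamma(2.0, 50.0, 500)
    mv = moments(vals)
    assert mv.skewness == pytest.approx(stats.skew(vals, bias=True), rel=1e-10)
    assert mv.kurtosis == pytest.approx(
        stats.kurtosis(vals, fisher=True, bias=True), rel=1e-10
    )


def test_moments_location_shift(rng):
    vals = rng.gamma(2.0, 50.0, 400)
    a, b = moments(vals), moments(vals + 111.0)
    assert b.mean == pytest.approx(a.mean + 111.0)
    assert b.dispersion == pytest.approx(a.dispersion)
    assert b.skewness == pytest.approx(a.skewness)
    assert b.kurtosis == pytest.approx(a.kurtosis)


def test_moment_difference_table(rng):
    obs = pd.DataFrame(
        {
            "participant_id": np.repeat([1, 2], 100),
            "condition": "baseline",
            "rt_ms": rng.uniform(400, 900, 200),
        }
    )
    same = moment_difference_table(obs, obs)
    assert np.allclose(same[["mean", "dispersion", "skewness", "kurtosis"]], 0.0)
    shifted = obs.assign(rt_ms=obs["rt_ms"] + 5.0)
    diff = moment_difference_table(shifted, obs)
    assert np.allclose(diff["mean"], 5.0)
    assert np.allclose(diff[["dispersion", "skewness", "kurtosis"]], 0.0, atol=1e-9)
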