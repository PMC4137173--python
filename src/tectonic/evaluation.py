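"""Model evaluation: Vincentized RT distributions and distributional moments.

Each participant's RTs are sorted and cut into 20 consecutive quantile bins
(5% each); bin means are averaged across participants to give the group
distribution for a condition.  Inter-quantile densities P(i) = 50 /
(RT(i+1) - RT(i)) turn the 20 group quantile means into a 19-point density
profile, compared between observed and predicted RTs by a chi-square
statistic conventionally evaluated on 17 degrees of freedom.  Trial-level
agreement is summarised by the first four moments with population
denominators and excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITIONS

__all__ = [
    "MomentSet",
    "N_QUANTILES",
    "CHI_SQUARE_DF",
    "vincentize",
    "group_distribution",
    "density",
    "chi_square_gof",
    "moments",
    "moment_difference_table",
    "condition_report",
]

N_QUANTILES = 20
# 19 density cells minus two constraints; the convention is isolated here so
# it can be swapped if a different accounting is preferred.
CHI_SQUARE_DF = 17


@dataclass(frozen=True)
class MomentSet:
    """Mean, dispersion (SD, ms), skewness and excess kurtosis of an RT
    collection, all with population (divide-by-n) denominators."""

    mean: float
    dispersion: float
    skewness: float
    kurtosis: float

    def __post_init__(self) -> None:
        assert self.dispersion >= 0
        assert self.kurtosis >= -2

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.dispersion, self.skewness, self.kurtosis])


def vincentize(rts, n_quantiles: int = N_QUANTILES) -> np.ndarray:
    """Quantile means of one participant's RTs.

    Sorts ascending and partitions into ``n_quantiles`` consecutive bins of
    size floor(n/q), the remainder going one-each to the earliest bins; the
    mean of each bin is its quantile RT.  Requires at least one RT per bin.
    """
    rts = np.sort(np.asarray(rts, dtype=float))
    n = rts.size
    if n < n_quantiles:
        raise ValueError(f"need >= {n_quantiles} RTs, got {n}")
    base, rem = divmod(n, n_quantiles)
    sizes = np.full(n_quantiles, base)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return np.array(
        [rts[edges[i]:edges[i + 1]].mean() for i in range(n_quantiles)]
    )


def group_distribution(per_participant: np.ndarray) -> np.ndarray:
    """Average quantile means across participants (rows) quantile-by-quantile."""
    arr = np.atleast_2d(np.asarray(per_participant, dtype=float))
    return arr.mean(axis=0)


def density(group_quantiles) -> np.ndarray:
    """Inter-quantile densities P(i) = 50 / (RT(i+1) - RT(i)), i = 1..19.

    A zero spacing yields an infinite density, surfaced as ``inf`` with a
    warning-free flag left to the caller (chi-square will propagate it).
    """
    q = np.asarray(group_quantiles, dtype=float)
    spacing = np.diff(q)
    if np.any(spacing < 0):
        raise ValueError("group quantile means must be nondecreasing")
    with np.errstate(divide="ignore"):
        return np.where(spacing > 0, 50.0 / spacing, np.inf)


def chi_square_gof(observed_quantiles, predicted_quantiles) -> tuple[float, int]:
    """Chi-square between observed and predicted group distributions.

    Computed over the 19 inter-quantile densities:
    ``sum (P_obs - P_pred)**2 / P_pred`` with df = 17.
    """
    p_obs = density(observed_quantiles)
    p_pred = density(predicted_quantiles)
    stat = float(np.sum((p_obs - p_pred) ** 2 / p_pred))
    return stat, CHI_SQUARE_DF


def moments(rts) -> MomentSet:
    """First four moments with population denominators; kurtosis is excess
    (the normal distribution scores 0)."""
    arr = np.asarray(rts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty RT collection")
    mean = float(arr.mean())
    dev = arr - mean
    var = float(np.mean(dev**2))
    disp = float(np.sqrt(var))
    if disp == 0:
        return MomentSet(mean, 0.0, 0.0, -2.0)
    skew = float(np.mean(dev**3) / disp**3)
    kurt = float(np.mean(dev**4) / disp**4 - 3.0)
    return MomentSet(mean, disp, skew, kurt)


def moment_difference_table(predicted: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Predicted-minus-observed moments per participant and condition.

    Both inputs need columns participant_id, condition, rt_ms.  Rows align
    on (participant_id, condition); a group summary is the column mean per
    condition of the returned table.
    """
    rows = []
    keys = ["participant_id", "condition"]
    obs_groups = observed.groupby(keys)["rt_ms"]
    for (pid, cond), pred_rts in predicted.groupby(keys)["rt_ms"]:
        obs_rts = obs_groups.get_group((pid, cond))
        d = moments(pred_rts.to_numpy()).as_array() - moments(obs_rts.to_numpy()).as_array()
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "mean": d[0],
                "dispersion": d[1],
                "skewness": d[2],
                "kurtosis": d[3],
            }
        )
    return pd.DataFrame(rows)


def condition_report(predicted_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition goodness-of-fit report from a predicted-trials table
    (columns participant_id, condition, rt_obs_ms, rt_pred_ms).

    Returns one row per condition with the 20 observed and predicted group
    quantile means, the 19+19 densities, and the chi-square statistic.
    """
    rows = []
    for cond in CONDITIONS:
        sub = predicted_trials[predicted_trials["condition"] == cond]
        if sub.empty:
            continue
        obs = np.vstack(
            [
                vincentize(g["rt_obs_ms"].to_numpy())
                for _, g in sub.groupby("participant_id")
            ]
        )
        pred = np.vstack(
            [
                vincentize(g["rt_pred_ms"].to_numpy())
                for _, g in sub.groupby("participant_id")
            ]
        )
        q_obs = group_distribution(obs)
        q_pred = group_distribution(pred)
        stat, df = chi_square_gof(q_obs, q_pred)
        row: dict = {"condition": cond, "chi_square": stat, "df": df}
        for i in range(N_QUANTILES):
            row[f"obs_q{i + 1:02d}"] = q_obs[i]
            row[f"pred_q{i + 1:02d}"] = q_pred[i]
        for i, (po, pp) in enumerate(zip(density(q_obs), density(q_pred)), start=1):
            row[f"obs_p{i:02d}"] = po
            row[f"pred_p{i:02d}"] = pp
        rows.append(row)
    return pd.DataFrame(rows)
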