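"""Activation dynamics, evidence computation, and RT prediction.

The model assumes that presenting a target tone simultaneously excites the
representation of that target and inhibits the representations of the two
non-presented targets and of the distractor set.  Each activation follows a
tenth-power logistic time course; a decision is emitted when the log-ratio
weight of evidence for the presented target reaches the stopping rule
``beta``.  The number of 1-ms cycles needed to reach threshold is the
predicted reaction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelConstants",
    "SlopeSet",
    "StartParams",
    "MaxCyclesExceeded",
    "act_target",
    "act_nontarget",
    "act_distractor",
    "evidence",
    "evidence_curve",
    "predict_rt",
    "predict_rt_scan",
    "target_slope",
    "distractor_slope",
    "DEFAULT_CONSTANTS",
]


class MaxCyclesExceeded(RuntimeError):
    """Evidence never reached the stopping rule within ``max_cycles``."""


@dataclass(frozen=True)
class ModelConstants:
    """Fixed constants shared by every model variant.

    Attributes
    ----------
    asymptote_exponent
        Power applied to the logistic activation function (10).
    evidence_constant
        Additive constant (6.0) keeping the evidence log-ratio finite and
        scaled to the stopping rule.
    slope_scale
        Multiplicative ceiling on activation slopes, per ms (0.023).
    threshold_beta
        Stopping rule on the weight of evidence (1.0).
    target_bound, nontarget_bound, distractor_bound
        Asymptotic activation bounds (+1, -1, -3).
    max_cycles
        Longest simulated decision time in ms before a trial is declared a
        non-crossing.
    """

    asymptote_exponent: int = 10
    evidence_constant: float = 6.0
    slope_scale: float = 0.023
    threshold_beta: float = 1.0
    target_bound: float = 1.0
    nontarget_bound: float = -1.0
    distractor_bound: float = -3.0
    max_cycles: int = 5000

    def __post_init__(self) -> None:
        # Denominator of the evidence ratio must stay positive at asymptote,
        # and the threshold must be reachable before it.
        inhib_total = abs(self.distractor_bound) + 2 * abs(self.nontarget_bound)
        if not self.evidence_constant > inhib_total:
            raise ValueError(
                "evidence_constant must exceed the summed inhibitory bounds "
                f"({inhib_total}); got {self.evidence_constant}"
            )
        sup = np.log(
            (self.target_bound + self.evidence_constant)
            / (
                self.evidence_constant
                + 2 * self.nontarget_bound
                + self.distractor_bound
            )
        )
        if not self.threshold_beta < sup:
            raise ValueError(
                f"threshold_beta={self.threshold_beta} is unreachable; "
                f"evidence supremum is {sup:.5f}"
            )


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class SlopeSet:
    """Per-trial activation slopes (ms^-1), one per target plus the shared
    distractor slope."""

    slope_t1: float
    slope_t2: float
    slope_t3: float
    slope_d: float

    @property
    def targets(self) -> np.ndarray:
        return np.array([self.slope_t1, self.slope_t2, self.slope_t3])

    def __post_init__(self) -> None:
        for v in (self.slope_t1, self.slope_t2, self.slope_t3, self.slope_d):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"slopes must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class StartParams:
    """Start/swell parameters governing trial-to-trial slope variability.

    Each slope is ``logistic(start + swell * x) * 0.023`` where ``x`` is the
    trial's noise value: the start parameter sets the baseline slope level
    (long-term memory influence) and the swell parameter its sensitivity to
    momentary noise.  Signs are unconstrained; the rank pairing of noise to
    RTs resolves the sign during estimation.
    """

    tstart: tuple[float, float, float]
    tswell: float
    dstart: float
    dswell: float

    def __post_init__(self) -> None:
        vals = (*self.tstart, self.tswell, self.dstart, self.dswell)
        if len(self.tstart) != 3 or not np.all(np.isfinite(vals)):
            raise ValueError("StartParams require three finite tstart values "
                             "and finite tswell/dstart/dswell")

    def slopes(self, x: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> SlopeSet:
        """The trial's four activation slopes for noise value ``x``."""
        t1, t2, t3 = (
            target_slope(s, self.tswell, x, constants) for s in self.tstart
        )
        return SlopeSet(t1, t2, t3, distractor_slope(self.dstart, self.dswell, x, constants))

    def as_array(self) -> np.ndarray:
        return np.array([*self.tstart, self.tswell, self.dstart, self.dswell])

    @classmethod
    def from_array(cls, theta) -> "StartParams":
        t1, t2, t3, tswell, dstart, dswell = map(float, theta)
        return cls((t1, t2, t3), tswell, dstart, dswell)


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input")


def act_target(slope, t, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Excitatory activation of the presented target at time ``t`` (ms).

    ``1 / (1 + exp(-slope * t)) ** k`` with ``k = 10``: a logistic rise from
    ``(1/2)**10`` at stimulus onset toward the asymptotic bound +1.
    Accepts scalars or broadcastable arrays.
    """
    _check_finite(slope, t)
    return expit(np.asarray(slope) * np.asarray(t)) ** constants.asymptote_exponent


def act_nontarget(slope, t, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Inhibitory activation of a non-presented target: the mirror image of
    :func:`act_target`, decreasing toward -1."""
    return -act_target(slope, t, constants)


def act_distractor(slope_d, t, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Inhibitory activation of the distractor set, with the bound elevated
    to -3 because one shared slope stands in for three distractors."""
    return constants.distractor_bound * act_target(slope_d, t, constants)


def evidence(
    slopes: SlopeSet,
    presented: int,
    t,
    constants: ModelConstants = DEFAULT_CONSTANTS,
):
    """Weight of evidence for the presented target at time ``t``.

    Log ratio of the presented target's excitatory activation (plus the
    evidence constant) to the summed inhibitory activations of the
    non-presented targets and distractors (plus the same constant).

    Parameters
    ----------
    slopes
        The trial's four activation slopes.
    presented
        Index of the presented target, 1..3.
    t
        Time in ms; scalar or array.
    """
    if presented not in (1, 2, 3):
        raise ValueError(f"presented target index must be 1..3, got {presented}")
    t = np.asarray(t, dtype=float)
    _check_finite(t)
    c = constants.evidence_constant
    tslopes = slopes.targets
    num = act_target(tslopes[presented - 1], t, constants) + c
    den = np.full_like(num, c, dtype=float)
    for j in range(3):
        if j != presented - 1:
            den += act_nontarget(tslopes[j], t, constants)
    den += act_distractor(slopes.slope_d, t, constants)
    assert np.all(den > 0), "evidence denominator must stay positive"
    return np.log(num / den)


def evidence_curve(slopes: SlopeSet, presented: int, t_grid, **kw):
    """Vectorised alias of :func:`evidence` for a grid of times."""
    return evidence(slopes, presented, np.asarray(t_grid, dtype=float), **kw)


def target_slope(tstart, tswell, x, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Trial slope of a target's activation: ``logistic(tstart + tswell*x)``
    scaled by the 0.023 ceiling.  ``x`` is the trial's noise value."""
    _check_finite(tstart, tswell, x)
    return expit(np.asarray(tstart) + np.asarray(tswell) * np.asarray(x)) * constants.slope_scale


def distractor_slope(dstart, dswell, x, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Trial slope of the shared distractor activation (same form as
    :func:`target_slope`)."""
    return target_slope(dstart, dswell, x, constants)


def predict_rt(
    slopes: SlopeSet,
    presented: int = 1,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-9,
) -> float:
    """Predicted RT: the smallest time at which evidence reaches beta.

    Solved by continuous bisection on the monotone evidence curve to an
    evidence residual below ``tol``.  Raises :class:`MaxCyclesExceeded` when
    the threshold is not crossed within ``max_cycles`` ms.
    """
    beta = constants.threshold_beta
    ev0 = float(evidence(slopes, presented, 0.0, constants))
    if ev0 >= beta:
        return 0.0
    lo, hi = 0.0, float(constants.max_cycles)
    ev_hi = float(evidence(slopes, presented, hi, constants))
    if ev_hi < beta:
        raise MaxCyclesExceeded(
            f"evidence {ev_hi:.6f} below beta={beta} at t={hi:.0f} ms"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        ev = float(evidence(slopes, presented, mid, constants))
        if abs(ev - beta) <= tol:
            return mid
        if ev < beta:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return hi


def predict_rt_scan(
    slopes: SlopeSet,
    presented: int = 1,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> int:
    """Integer-cycle RT solver: iterate t = 0, 1, 2, ... and return the first
    cycle at which evidence reaches beta.  Used as an oracle for the
    continuous solver."""
    t_grid = np.arange(constants.max_cycles + 1, dtype=float)
    ev = evidence(slopes, presented, t_grid, constants)
    crossed = ev >= constants.threshold_beta
    if not crossed.any():
        raise MaxCyclesExceeded(
            f"no crossing within {constants.max_cycles} cycles"
        )
    return int(np.argmax(crossed))
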