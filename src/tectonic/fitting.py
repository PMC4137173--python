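"""Two-stage model estimation: objective minimisation, then per-trial backfit.

Stage one estimates the start/swell parameters by Nelder-Mead minimisation
of the summed squared evidence residual at the observed RTs.  Stage two
(the backfit) inserts the estimates back into the slope equations with time
as the unknown and solves trial-by-trial for the threshold-crossing time,
which is the model's predicted RT for that trial.

Four variants are supported.  ``inhibition_only`` re-fits the distractor
start parameter in each filtering condition (9 free parameters);
``excitation_only`` re-fits the three target start parameters per condition
(15); the EEG-linked ``rp`` and ``pn`` variants replace those per-condition
parameters with a two-parameter linear regression on condition-mean
slow-wave amplitude (7 and 9 free parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from . import eeg
from .design import BASELINE, CONDITIONS, FILTERING
from .model import (
    DEFAULT_CONSTANTS,
    MaxCyclesExceeded,
    ModelConstants,
    StartParams,
)

__all__ = [
    "ModelSpec",
    "RegressionLink",
    "FitResult",
    "ParticipantFit",
    "FREE_PARAM_COUNTS",
    "VARIANTS",
    "NOISE_SOURCES",
    "trial_evidence",
    "objective",
    "sample_noise",
    "assign_noise",
    "backfit_rts",
    "fit_link",
    "apply_link",
    "fit_participant",
    "fit_dataset",
    "backfit_dataset",
]

logger = logging.getLogger(__name__)

VARIANTS = ("inhibition_only", "excitation_only", "rp", "pn")
NOISE_SOURCES = ("gaussian", "rectangular", "rp_noise")

FREE_PARAM_COUNTS = {
    "inhibition_only": 9,
    "excitation_only": 15,
    "rp": 7,
    "pn": 9,
}


@dataclass(frozen=True)
class ModelSpec:
    """Which variant to fit and which stochastic source drives the trials."""

    variant: str = "inhibition_only"
    noise_source: str = "gaussian"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.noise_source not in NOISE_SOURCES:
            raise ValueError(f"unknown noise source {self.noise_source!r}")

    @property
    def n_free_params(self) -> int:
        return FREE_PARAM_COUNTS[self.variant]


@dataclass(frozen=True)
class RegressionLink:
    """Linear link from condition-mean slow-wave amplitude to a start
    parameter, fitted per participant from the four condition points."""

    parameter: str
    intercept: float
    coefficient: float


@dataclass
class FitResult:
    """Outcome of one Nelder-Mead estimation."""

    theta: np.ndarray
    objective: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        assert self.objective >= 0


@dataclass
class ParticipantFit:
    """Everything needed to backfit one participant: per-condition parameters
    and the rank-paired noise assignment used during estimation."""

    participant_id: int
    spec: ModelSpec
    seed: int
    params: dict[str, StartParams] = field(default_factory=dict)
    objectives: dict[str, float] = field(default_factory=dict)
    converged: dict[str, bool] = field(default_factory=dict)
    # per condition: (trial_index array, x array) aligned element-wise
    noise: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    links: list[RegressionLink] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Vectorised trial-level evidence
# ---------------------------------------------------------------------------

def trial_evidence(
    params: StartParams,
    presented: np.ndarray,
    x: np.ndarray,
    t: np.ndarray,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Evidence for the presented target on each trial at trial time ``t``.

    ``presented`` holds 1-based target indices; ``x`` the per-trial noise
    value shared by all four slope computations of that trial; ``t`` the
    per-trial evaluation time in ms (broadcastable against ``x``).
    """
    presented = np.asarray(presented, dtype=int)
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    k = constants.asymptote_exponent
    c = constants.evidence_constant
    tstart = np.asarray(params.tstart)
    slopes_t = expit(tstart[None, :] + params.tswell * x[:, None]) * constants.slope_scale
    slope_d = expit(params.dstart + params.dswell * x) * constants.slope_scale
    act_t = expit(slopes_t * t[..., None]) ** k          # (n, 3)
    act_d = expit(slope_d * t) ** k
    idx = presented - 1
    rows = np.arange(act_t.shape[0])
    num = act_t[rows, idx] + c
    den = c - (act_t.sum(axis=1) - act_t[rows, idx]) + constants.distractor_bound * act_d
    return np.log(num / den)


def objective(
    params: StartParams,
    rt_obs: np.ndarray,
    presented: np.ndarray,
    x: np.ndarray,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Summed squared evidence residual at the observed RTs:
    ``sum_h (beta - Evidence(T_i(h), rt_h))**2``."""
    ev = trial_evidence(params, presented, x, np.asarray(rt_obs, dtype=float), constants)
    return float(np.sum((constants.threshold_beta - ev) ** 2))


def backfit_rts(
    params: StartParams,
    presented: np.ndarray,
    x: np.ndarray,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-9,
    on_no_crossing: str = "raise",
) -> np.ndarray:
    """Per-trial threshold-crossing time (predicted RT) by vectorised
    bisection on the monotone evidence curve.

    A trial whose evidence never reaches beta within ``max_cycles`` ms has
    its squared evidence residual minimized at the horizon itself; with
    ``on_no_crossing='clip'`` such trials return ``max_cycles`` (counted and
    logged), while the default raises
    :class:`~tectonic.model.MaxCyclesExceeded`.
    """
    presented = np.asarray(presented, dtype=int)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    beta = constants.threshold_beta
    hi = np.full(n, float(constants.max_cycles))
    lo = np.zeros(n)
    ev_hi = trial_evidence(params, presented, x, hi, constants)
    if np.any(ev_hi < beta):
        bad = int(np.sum(ev_hi < beta))
        if on_no_crossing != "clip":
            raise MaxCyclesExceeded(
                f"{bad} trial(s) never reach beta={beta} within "
                f"{constants.max_cycles} ms"
            )
        logger.warning(
            "%d trial(s) never reach beta=%s within %d ms; "
            "returning the horizon as the objective-minimizing time",
            bad, beta, constants.max_cycles,
        )
    ev_lo = trial_evidence(params, presented, x, lo, constants)
    already = ev_lo >= beta
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        ev = trial_evidence(params, presented, x, mid, constants)
        below = ev < beta
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.all((hi - lo) < tol):
            break
    out = hi
    return np.where(already, 0.0, out)


# ---------------------------------------------------------------------------
# Noise handling
# ---------------------------------------------------------------------------

def sample_noise(
    source: str,
    n: int,
    seed,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n`` per-trial noise values from the requested source.

    gaussian: standard normal draws; rectangular: uniform on [-sqrt(3),
    sqrt(3)] (zero mean, unit variance); rp_noise: ``n`` evenly spaced order
    statistics of ``pool`` — the rescaled single-trial RP amplitudes.  The
    deterministic quantile thinning keeps the selected set distributionally
    faithful to the pool (including its extremes) whatever the mismatch
    between pool size and trial count; values repeat when the pool is
    smaller than the trial count (logged).
    """
    rng = np.random.default_rng(seed)
    if source == "gaussian":
        return rng.standard_normal(n)
    if source == "rectangular":
        half = np.sqrt(3.0)
        return rng.uniform(-half, half, n)
    if source == "rp_noise":
        if pool is None:
            raise ValueError("rp_noise requires a pool of rescaled amplitudes")
        pool = np.sort(np.asarray(pool, dtype=float))
        if pool.size < n:
            logger.info(
                "rp_noise pool (%d) smaller than trial count (%d); "
                "order statistics will repeat", pool.size, n,
            )
        idx = np.round(np.linspace(0, pool.size - 1, n)).astype(int)
        return pool[idx]
    raise ValueError(f"unknown noise source {source!r}")


def assign_noise(noise: np.ndarray, rt_obs: np.ndarray) -> np.ndarray:
    """Rank-pair noise values to trials: the smallest noise value goes to the
    trial with the shortest RT, and so on.  Ties in RT keep original trial
    order (stable sort).  Returns x aligned with the input trial order."""
    noise = np.asarray(noise, dtype=float)
    rt_obs = np.asarray(rt_obs, dtype=float)
    if noise.shape[0] != rt_obs.shape[0]:
        raise ValueError("noise and RT counts must match")
    order = np.argsort(rt_obs, kind="stable")
    x = np.empty_like(noise)
    x[order] = np.sort(noise)
    return x


# ---------------------------------------------------------------------------
# Regression links
# ---------------------------------------------------------------------------

def fit_link(
    param_values: np.ndarray,
    amplitudes: np.ndarray,
    parameter: str,
) -> RegressionLink:
    """Ordinary least squares of a start parameter on condition-mean
    amplitude (amplitude as predictor), one point per condition."""
    y = np.asarray(param_values, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ValueError("need matching 1-D parameter and amplitude vectors")
    var = np.var(a)
    if var == 0:
        return RegressionLink(parameter, float(np.mean(y)), 0.0)
    coef = float(np.cov(a, y, bias=True)[0, 1] / var)
    intercept = float(np.mean(y) - coef * np.mean(a))
    return RegressionLink(parameter, intercept, coef)


def apply_link(link: RegressionLink, amplitude: float) -> float:
    """Start parameter implied by a condition's mean amplitude."""
    return link.intercept + link.coefficient * float(amplitude)


# ---------------------------------------------------------------------------
# Nelder-Mead estimation
# ---------------------------------------------------------------------------

_NM_OPTIONS = {"xatol": 1e-8, "fatol": 1e-8, "maxiter": 20000, "maxfev": 20000}
N_RESTARTS = 6
N_PROBES = 512


def _minimize_multistart(fun, x0: np.ndarray, rng: np.random.Generator,
                         n_restarts: int = N_RESTARTS,
                         return_all: bool = False):
    """Nelder-Mead restarted from the most promising seeded starting points.

    The objective surface has flat ridges and saturated regions (slopes pinned
    at 0 or the 0.023 ceiling), so a single simplex start is unreliable.  A
    cheap probe of ``N_PROBES`` seeded candidate points around the canonical
    start selects the ``n_restarts`` best basins; Nelder-Mead polishes each.
    Returns the best minimum, or all minima sorted by objective when
    ``return_all`` (the baseline ridge is near-flat, so downstream stages may
    need to disambiguate candidates by cross-condition fit).
    """
    half = N_PROBES // 2
    probes = np.vstack(
        [
            x0 + rng.normal(0.0, 0.75, size=(half, x0.shape[0])),
            x0 + rng.normal(0.0, 1.5, size=(N_PROBES - half, x0.shape[0])),
        ]
    )
    probes[0] = x0
    scores = np.array([fun(p) for p in probes])
    starts = probes[np.argsort(scores)[:n_restarts]]
    results = []
    for start in starts:
        res = minimize(fun, start, method="Nelder-Mead", options=_NM_OPTIONS)
        results.append(
            FitResult(
                theta=np.asarray(res.x, dtype=float),
                objective=float(res.fun),
                converged=bool(res.success),
                n_iter=int(res.nit),
            )
        )
    results.sort(key=lambda r: r.objective)
    return results if return_all else results[0]


def _condition_trials(trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Correct target trials of one condition — the only trials simulated."""
    sub = trials[
        (trials["condition"] == condition)
        & (trials["stimulus_role"] == "target")
        & (trials["correct"].astype(int) == 1)
    ]
    return sub.dropna(subset=["rt_ms"])


def _rp_pools(
    trials: pd.DataFrame, amplitudes: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-condition rescaled RP-noise pools from valid distractor trials."""
    merged = amplitudes.merge(
        trials[["condition", "trial_index", "stimulus_role"]],
        on=["condition", "trial_index"],
        how="left",
    )
    pools = {}
    for cond in CONDITIONS:
        sel = merged[
            (merged["condition"] == cond)
            & (merged["stimulus_role"] == "distractor")
            & (merged["valid"].astype(bool))
        ]["fz_mean_uv"].to_numpy()
        pools[cond], _ = eeg.rescale_noise(sel)
    return pools


def _mean_rp_amplitudes(
    trials: pd.DataFrame, amplitudes: pd.DataFrame
) -> dict[str, float]:
    """Condition-mean RP amplitude (valid distractor trials, raw µV)."""
    merged = amplitudes.merge(
        trials[["condition", "trial_index", "stimulus_role"]],
        on=["condition", "trial_index"],
        how="left",
    )
    out = {}
    for cond in CONDITIONS:
        sel = merged[
            (merged["condition"] == cond)
            & (merged["stimulus_role"] == "distractor")
            & (merged["valid"].astype(bool))
        ]["fz_mean_uv"]
        out[cond] = float(sel.mean())
    return out


def _mean_pn_amplitudes(
    trials: pd.DataFrame, amplitudes: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Condition-mean PN amplitude per target level (valid target trials)."""
    merged = amplitudes.merge(
        trials[["condition", "trial_index", "stimulus_role", "stimulus_level"]],
        on=["condition", "trial_index"],
        how="left",
    )
    out = {}
    for cond in CONDITIONS:
        means = np.empty(3)
        for lvl in (1, 2, 3):
            sel = merged[
                (merged["condition"] == cond)
                & (merged["stimulus_role"] == "target")
                & (merged["stimulus_level"] == lvl)
                & (merged["valid"].astype(bool))
            ]["fz_mean_uv"]
            means[lvl - 1] = float(sel.mean())
        out[cond] = means
    return out


_SATURATION_LIMIT = 6.0


def _saturation_penalty(params: StartParams, x: np.ndarray) -> float:
    """Soft barrier keeping every realized slope strictly inside the open
    interval (0, slope_scale).

    Slopes are logistic transforms of ``start + swell * x``; once that
    argument leaves its responsive range the slope pins to 0 or the ceiling
    and the parameters lose meaning, creating flat degenerate basins in the
    objective.  Quadratic growth beyond |argument| = 6 steers the simplex
    away without affecting any interior solution.
    """
    args = np.concatenate(
        [
            (np.asarray(params.tstart)[None, :] + params.tswell * x[:, None]).ravel(),
            params.dstart + params.dswell * x,
        ]
    )
    excess = np.maximum(np.abs(args) - _SATURATION_LIMIT, 0.0)
    return float(np.sum(excess**2))


_BASELINE_X0 = np.array([0.0, 0.0, 0.0, 0.5, 0.0, 0.5])


def fit_participant(
    trials: pd.DataFrame,
    spec: ModelSpec,
    seed: int,
    amplitudes: pd.DataFrame | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ParticipantFit:
    """Run the two-stage estimation for one participant.

    ``trials`` and ``amplitudes`` must contain exactly one participant.
    The baseline condition is fitted first with six free parameters; the
    variant then determines which parameters are re-fitted, carried, or
    replaced by the amplitude regression link in the filtering conditions.
    """
    pid = trials["participant_id"].unique()
    if pid.size != 1:
        raise ValueError("fit_participant expects a single participant")
    pid = int(pid[0])
    needs_eeg = spec.noise_source == "rp_noise" or spec.variant in ("rp", "pn")
    if needs_eeg and amplitudes is None:
        raise ValueError(
            f"{spec.variant}/{spec.noise_source} requires an amplitudes table"
        )

    ss = np.random.SeedSequence(seed)
    noise_ss, nm_ss = ss.spawn(2)
    noise_children = dict(zip(CONDITIONS, noise_ss.spawn(len(CONDITIONS))))
    nm_rng = np.random.default_rng(nm_ss)

    pools = _rp_pools(trials, amplitudes) if spec.noise_source == "rp_noise" else {}

    fit = ParticipantFit(participant_id=pid, spec=spec, seed=seed)
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for cond in CONDITIONS:
        sub = _condition_trials(trials, cond)
        if len(sub) < 2:
            raise ValueError(f"too few correct target trials in {cond!r}")
        rts = sub["rt_ms"].to_numpy(dtype=float)
        presented = sub["stimulus_level"].to_numpy(dtype=int)
        noise = sample_noise(
            spec.noise_source, len(sub), noise_children[cond], pools.get(cond)
        )
        x = assign_noise(noise, rts)
        data[cond] = (rts, presented, x)
        fit.noise[cond] = (sub["trial_index"].to_numpy(), x)
        logger.info("participant %d %s: %d correct target trials", pid, cond, len(sub))

    def obj_for(cond, builder):
        rts, presented, x = data[cond]

        def fun(theta):
            p = builder(theta)
            return objective(p, rts, presented, x, constants) + _saturation_penalty(p, x)

        return fun

    # Stage 1a: six free parameters at baseline.  The baseline objective has
    # a near-flat ridge (any parameters reproducing the monotone noise-to-RT
    # curve fit one condition equally well), so all multistart minima are
    # kept and the one whose carried parameters generalize best across the
    # filtering conditions — measured by the total objective after the
    # variant's own per-condition refits — is selected.
    candidates = _minimize_multistart(
        obj_for(BASELINE, StartParams.from_array), _BASELINE_X0, nm_rng,
        return_all=True,
    )
    # The tie-break extends each candidate by the smallest possible
    # per-condition change — one distractor start parameter per filtering
    # condition — and scores the total objective across all four conditions.
    # The same rule applies whatever variant is being fitted, so every
    # variant carries an identical baseline fit.
    best = None
    for cand in candidates:
        cand_base = StartParams.from_array(cand.theta)
        cand_fits = _fit_inhibition(cand_base, data, obj_for, nm_rng)
        total = cand.objective + sum(res.objective for _, res in cand_fits.values())
        if best is None or total < best[0]:
            best = (total, cand, cand_base, cand_fits)
    _, base_res, base, inh_per_cond = best
    per_cond = (
        inh_per_cond
        if spec.variant in ("inhibition_only", "rp")
        else _fit_excitation(base, data, obj_for, nm_rng)
    )

    fit.params[BASELINE] = base
    fit.objectives[BASELINE] = base_res.objective
    fit.converged[BASELINE] = base_res.converged

    # Stage 1b: variant-specific filtering-condition parameters.
    if spec.variant in ("inhibition_only", "excitation_only"):
        _store(fit, per_cond)
    elif spec.variant == "rp":
        _fit_rp(fit, base, per_cond, trials, amplitudes, data, nm_rng, constants)
    else:
        _fit_pn(fit, base, per_cond, trials, amplitudes, data, nm_rng, constants)
    return fit


def _store(fit: ParticipantFit, results: dict[str, tuple[StartParams, FitResult]]):
    for cond, (params, res) in results.items():
        fit.params[cond] = params
        fit.objectives[cond] = res.objective
        fit.converged[cond] = res.converged


def _fit_inhibition(base, data, obj_for, rng):
    """Re-fit dstart per filtering condition; all else carried from baseline."""
    out = {}
    for cond in FILTERING:
        def build(theta, base=base):
            return StartParams(base.tstart, base.tswell, float(theta[0]), base.dswell)
        res = _minimize_multistart(obj_for(cond, build), np.array([base.dstart]), rng)
        out[cond] = (build(res.theta), res)
    return out


def _fit_excitation(base, data, obj_for, rng):
    """Re-fit the three tstart per filtering condition; all else carried."""
    out = {}
    for cond in FILTERING:
        def build(theta, base=base):
            return StartParams(tuple(map(float, theta)), base.tswell,
                               base.dstart, base.dswell)
        res = _minimize_multistart(obj_for(cond, build), np.asarray(base.tstart), rng)
        out[cond] = (build(res.theta), res)
    return out


def _fit_rp(fit, base, inh, trials, amplitudes, data, rng, constants):
    """RP variant: dstart in every condition comes from a 2-parameter
    regression of the inhibition-only dstart estimates on condition-mean RP
    amplitude; tstart/tswell/dswell are then re-estimated at baseline with
    the linked dstart held fixed, and carried to all conditions."""
    amps = _mean_rp_amplitudes(trials, amplitudes)
    dstarts = np.array(
        [base.dstart if c == BASELINE else inh[c][0].dstart for c in CONDITIONS]
    )
    amp_vec = np.array([amps[c] for c in CONDITIONS])
    link = fit_link(dstarts, amp_vec, "dstart")
    fit.links.append(link)
    linked = {c: apply_link(link, amps[c]) for c in CONDITIONS}

    rts, presented, x = data[BASELINE]

    def build(theta):
        t1, t2, t3, tswell, dswell = map(float, theta)
        return StartParams((t1, t2, t3), tswell, linked[BASELINE], dswell)

    x0 = np.array([*base.tstart, base.tswell, base.dswell])
    res = _minimize_multistart(
        lambda th: objective(build(th), rts, presented, x, constants)
        + _saturation_penalty(build(th), x),
        x0,
        rng,
    )
    refit = build(res.theta)
    for cond in CONDITIONS:
        fit.params[cond] = StartParams(
            refit.tstart, refit.tswell, linked[cond], refit.dswell
        )
        r, p, xc = data[cond]
        fit.objectives[cond] = objective(fit.params[cond], r, p, xc, constants)
        fit.converged[cond] = res.converged


def _fit_pn(fit, base, exc, trials, amplitudes, data, rng, constants):
    """PN variant: each tstart comes from its own regression of the
    excitation-only tstart estimates on condition-mean PN amplitude for that
    target; tswell/dstart/dswell are re-estimated at baseline and carried."""
    amps = _mean_pn_amplitudes(trials, amplitudes)
    linked: dict[str, np.ndarray] = {c: np.empty(3) for c in CONDITIONS}
    for i in range(3):
        tstarts = np.array(
            [base.tstart[i] if c == BASELINE else exc[c][0].tstart[i]
             for c in CONDITIONS]
        )
        amp_vec = np.array([amps[c][i] for c in CONDITIONS])
        link = fit_link(tstarts, amp_vec, f"tstart_{i + 1}")
        fit.links.append(link)
        for c in CONDITIONS:
            linked[c][i] = apply_link(link, amps[c][i])

    rts, presented, x = data[BASELINE]

    def build(theta):
        tswell, dstart, dswell = map(float, theta)
        return StartParams(tuple(linked[BASELINE]), tswell, dstart, dswell)

    x0 = np.array([base.tswell, base.dstart, base.dswell])
    res = _minimize_multistart(
        lambda th: objective(build(th), rts, presented, x, constants)
        + _saturation_penalty(build(th), x),
        x0,
        rng,
    )
    refit = build(res.theta)
    for cond in CONDITIONS:
        fit.params[cond] = StartParams(
            tuple(linked[cond]), refit.tswell, refit.dstart, refit.dswell
        )
        r, p, xc = data[cond]
        fit.objectives[cond] = objective(fit.params[cond], r, p, xc, constants)
        fit.converged[cond] = res.converged


# ---------------------------------------------------------------------------
# Dataset-level drivers
# ---------------------------------------------------------------------------

def fit_dataset(
    trials: pd.DataFrame,
    spec: ModelSpec,
    seed: int,
    amplitudes: pd.DataFrame | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[int, ParticipantFit]:
    """Fit every participant independently with sub-seeds fanned out from
    ``seed`` in sorted participant order."""
    pids = sorted(trials["participant_id"].unique())
    children = np.random.SeedSequence(seed).spawn(len(pids))
    fits = {}
    for pid, child in zip(pids, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        t = trials[trials["participant_id"] == pid]
        a = (
            amplitudes[amplitudes["participant_id"] == pid]
            if amplitudes is not None
            else None
        )
        fits[pid] = fit_participant(t, spec, sub_seed, a, constants)
    return fits


def backfit_participant(
    fit: ParticipantFit,
    trials: pd.DataFrame,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Stage two for one participant: solve trial-by-trial for the
    threshold-crossing time using the fitted parameters and the rank-paired
    noise values from estimation."""
    frames = []
    for cond in CONDITIONS:
        sub = _condition_trials(trials, cond).set_index("trial_index")
        idx, x = fit.noise[cond]
        sub = sub.loc[idx]
        presented = sub["stimulus_level"].to_numpy(dtype=int)
        pred = backfit_rts(
            fit.params[cond], presented, x, constants, on_no_crossing="clip"
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": fit.participant_id,
                    "condition": cond,
                    "trial_index": idx,
                    "rt_obs_ms": sub["rt_ms"].to_numpy(dtype=float),
                    "rt_pred_ms": pred,
                    "x": x,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def backfit_dataset(
    fits: dict[int, ParticipantFit],
    trials: pd.DataFrame,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Predicted-trials table for a whole dataset."""
    return pd.concat(
        [
            backfit_participant(fit, trials[trials["participant_id"] == pid], constants)
            for pid, fit in sorted(fits.items())
        ],
        ignore_index=True,
    )
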