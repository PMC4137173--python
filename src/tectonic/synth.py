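"""Synthetic datasets emulating the auditory Garner-paradigm study.

Generates experiment-structured data with known ground truth: a randomized
trial schedule (4 conditions x 300 trials, 150 target + 150 distractor, 50
trials per stimulus), single-trial Fz slow-wave amplitudes whose condition
means decrease with distractor salience, and per-trial RTs produced by the
accumulation model itself from condition-linked start parameters.  Because
RTs come straight from the model with no added measurement noise, the
forward-simulate -> backfit roundtrip is exact, which is what makes every
pipeline stage testable without the unreleased human data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, eeg
from .fitting import backfit_rts, sample_noise
from .model import DEFAULT_CONSTANTS, ModelConstants, StartParams

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "default_truth",
    "make_design",
    "gen_amplitudes",
    "gen_epochs",
    "simulate_rts",
    "make_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class DesignSpec:
    """Structural parameters of the experiment."""

    n_participants: int = 11
    trials_per_stimulus: int = design.TRIALS_PER_STIMULUS
    isi_range_ms: tuple[float, float] = design.ISI_RANGE_MS


# Condition-mean slow-wave amplitudes (µV).  RP (distractor trials) decreases
# monotonically with distractor salience; PN (target trials) is a negativity
# whose magnitude shrinks as attention is captured by distractors.  The
# spacing follows the distractor-set frequency ranges of the four conditions
# (0, 78, 136, 191 Hz), so the baseline-to-filtering-1 step is the largest.
# These are generator defaults chosen to reproduce the qualitative salience
# pattern, not measured values.
RP_AMP_MEANS = {"baseline": 2.0, "filtering1": 1.39, "filtering2": 0.93, "filtering3": 0.5}
PN_AMP_MEANS = {"baseline": -2.0, "filtering1": -1.63, "filtering2": -1.36, "filtering3": -1.1}


@dataclass
class GroundTruth:
    """Generative parameters, serialized alongside every synthetic dataset.

    ``params[pid][condition]`` holds the StartParams that generated that
    participant-condition; the distractor start parameter follows a linear
    link ``dstart = intercept_p + coefficient * rp_amp_mean[condition]`` so
    that the amplitude-to-parameter regression is recoverable by the fitting
    pipeline.
    """

    params: dict[int, dict[str, StartParams]]
    link_intercepts: dict[int, float]
    link_coefficient: float
    rp_amp_mean: dict[str, float] = field(default_factory=lambda: dict(RP_AMP_MEANS))
    pn_amp_mean: dict[str, float] = field(default_factory=lambda: dict(PN_AMP_MEANS))
    amp_sd: float = 1.0
    error_rate: float = 0.05
    artifact_rate: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        means = [self.rp_amp_mean[c] for c in design.CONDITIONS]
        if not all(a > b for a, b in zip(means, means[1:])):
            raise ValueError("RP condition means must decrease with salience")

    def to_json(self) -> str:
        # asdict recurses into the nested StartParams; json stringifies the
        # integer participant keys.
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["params"] = {
            int(pid): {
                c: StartParams(tuple(p["tstart"]), p["tswell"], p["dstart"], p["dswell"])
                for c, p in by_cond.items()
            }
            for pid, by_cond in d["params"].items()
        }
        d["link_intercepts"] = {int(k): v for k, v in d["link_intercepts"].items()}
        return cls(**d)


def default_truth(seed: int, spec: DesignSpec = DesignSpec()) -> GroundTruth:
    """Generative defaults for an 11-participant study.

    Start parameters are drawn once per participant around values that put
    simulated mean RTs in the several-hundred-ms range of a speeded auditory
    identification task; swell parameters are negative so larger noise
    values slow the trial, matching the rank-pairing convention (smallest x
    with the shortest RT).  The three target start parameters sit close
    together: the targets are counterbalanced, well-discriminable tones, and
    the estimation stage's rank pairing pools RTs across targets, which
    presumes target-specific speed differences are second-order relative to
    trial noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7274]))
    coef = 0.7
    params: dict[int, dict[str, StartParams]] = {}
    intercepts: dict[int, float] = {}
    for pid in range(1, spec.n_participants + 1):
        tstart = tuple(
            np.array([-0.01, -0.05, -0.09]) + rng.normal(0.0, 0.03, 3)
        )
        intercept = -2.40 + rng.normal(0.0, 0.08)
        intercepts[pid] = intercept
        by_cond = {}
        for cond in design.CONDITIONS:
            dstart = intercept + coef * RP_AMP_MEANS[cond]
            by_cond[cond] = StartParams(tstart, -0.20, dstart, -0.35)
        params[pid] = by_cond
    return GroundTruth(
        params=params,
        link_intercepts=intercepts,
        link_coefficient=coef,
        master_seed=seed,
    )


def make_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Randomized trial schedule for every participant and condition.

    300 trials per condition: 50 per target stimulus (3 targets) and 50 per
    distractor stimulus (150 baseline trials of the single 1020 Hz
    distractor).  Onset-to-onset intervals are uniform on 1450-1600 ms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD351]))
    rows = []
    for pid in range(1, spec.n_participants + 1):
        for cond in design.CONDITIONS:
            stims: list[tuple[str, int, int]] = []
            for lvl, hz in enumerate(design.TARGET_HZ, start=1):
                stims += [("target", lvl, hz)] * spec.trials_per_stimulus
            dist = design.DISTRACTOR_HZ[cond]
            n_per = design.N_DISTRACTOR_TRIALS // len(dist)
            for lvl, hz in enumerate(dist, start=1):
                lvl = 2 if len(dist) == 1 else lvl  # baseline tone is D2
                stims += [("distractor", lvl, hz)] * n_per
            order = rng.permutation(len(stims))
            isi = rng.uniform(*spec.isi_range_ms, size=len(stims))
            for trial_index, j in enumerate(order):
                role, lvl, hz = stims[j]
                rows.append(
                    (pid, cond, trial_index, role, lvl, hz, isi[trial_index])
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "trial_index",
            "stimulus_role",
            "stimulus_level",
            "frequency_hz",
            "isi_ms",
        ],
    )


def gen_amplitudes(truth: GroundTruth, schedule: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Single-trial Fz window-mean amplitudes for every trial.

    Distractor trials draw around the condition RP mean, target trials
    around the condition PN mean, both with the trial-level SD from the
    ground truth; a small fraction is flagged invalid (artifact)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA321]))
    cond = schedule["condition"].to_numpy()
    role = schedule["stimulus_role"].to_numpy()
    mean = np.where(
        role == "distractor",
        [truth.rp_amp_mean[c] for c in cond],
        [truth.pn_amp_mean[c] for c in cond],
    )
    amp = mean + rng.normal(0.0, truth.amp_sd, size=len(schedule))
    valid = rng.random(len(schedule)) >= truth.artifact_rate
    out = schedule[["participant_id", "condition", "trial_index"]].copy()
    out["fz_mean_uv"] = amp
    out["valid"] = valid
    return out


def gen_epochs(amplitudes: pd.DataFrame, seed: int, background_sd: float = 2.0) -> pd.DataFrame:
    """Full 200-sample epochs consistent with an amplitudes table.

    Background noise everywhere, the slow wave injected so that the
    baseline-corrected 400-600 ms window mean reproduces ``fz_mean_uv``
    exactly, and a 150 µV spike (outside baseline and window) on trials
    flagged invalid so artifact rejection reproduces the ``valid`` flags.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEE06]))
    t = eeg.sample_times()
    pre = t < 0
    win = (t >= eeg.RP_WINDOW_MS[0]) & (t < eeg.RP_WINDOW_MS[1])
    n = len(amplitudes)
    samples = rng.normal(0.0, background_sd, size=(n, eeg.N_SAMPLES))
    samples[:, pre] -= samples[:, pre].mean(axis=1, keepdims=True)
    amp = amplitudes["fz_mean_uv"].to_numpy(dtype=float)
    samples[:, win] += amp[:, None] - samples[:, win].mean(axis=1, keepdims=True)
    spike_col = int(np.argmax(t == 100))
    samples[~amplitudes["valid"].to_numpy(dtype=bool), spike_col] = 150.0
    meta = amplitudes[["participant_id", "condition", "trial_index"]].reset_index(drop=True)
    wave = pd.DataFrame(samples, columns=eeg.SAMPLE_COLUMNS)
    return pd.concat([meta, wave], axis=1)


def simulate_rts(
    truth: GroundTruth,
    schedule: pd.DataFrame,
    noise_mode: str,
    seed: int,
    amplitudes: pd.DataFrame | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Forward-simulate trial RTs through the accumulation model.

    Per target trial, a noise value x is drawn (gaussian/rectangular) or
    taken from the participant-condition pool of rescaled valid distractor
    amplitudes (rp_noise); slopes follow from the ground-truth start/swell
    parameters and the RT is the threshold-crossing time.  Correctness is an
    independent Bernoulli flag; distractor trials carry no RT.  The
    generative x is kept in column ``x`` for roundtrip tests.
    """
    ss = np.random.SeedSequence([seed, 0x5172])
    trials = schedule.copy()
    trials["rt_ms"] = np.nan
    trials["correct"] = 1
    trials["x"] = np.nan
    pids = sorted(trials["participant_id"].unique())
    children = ss.spawn(len(pids) * len(design.CONDITIONS))
    k = 0
    for pid in pids:
        for cond in design.CONDITIONS:
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            mask = (
                (trials["participant_id"] == pid)
                & (trials["condition"] == cond)
                & (trials["stimulus_role"] == "target")
            )
            n = int(mask.sum())
            if noise_mode == "rp_noise":
                if amplitudes is None:
                    raise ValueError("rp_noise simulation needs an amplitudes table")
                sel = amplitudes.merge(
                    trials.loc[
                        (trials["participant_id"] == pid)
                        & (trials["condition"] == cond),
                        ["participant_id", "condition", "trial_index", "stimulus_role"],
                    ],
                    on=["participant_id", "condition", "trial_index"],
                )
                pool = sel[
                    (sel["stimulus_role"] == "distractor") & sel["valid"].astype(bool)
                ]["fz_mean_uv"].to_numpy()
                pool, _ = eeg.rescale_noise(pool)
                x = sample_noise("rp_noise", n, child, pool)
            else:
                x = sample_noise(noise_mode, n, child)
            params = truth.params[pid][cond]
            presented = trials.loc[mask, "stimulus_level"].to_numpy(dtype=int)
            rt = backfit_rts(params, presented, x, constants)
            trials.loc[mask, "rt_ms"] = rt
            trials.loc[mask, "x"] = x
            trials.loc[mask, "correct"] = (
                rng.random(n) >= truth.error_rate
            ).astype(int)
    return trials


def make_dataset(
    seed: int,
    noise_mode: str = "rp_noise",
    spec: DesignSpec = DesignSpec(),
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience one-call generator: schedule + amplitudes + simulated RTs."""
    if truth is None:
        truth = default_truth(seed, spec)
    schedule = make_design(spec, seed)
    amplitudes = gen_amplitudes(truth, schedule, seed)
    trials = simulate_rts(truth, schedule, noise_mode, seed, amplitudes)
    return trials, amplitudes, truth


TRIALS_COLUMNS = [
    "participant_id", "condition", "trial_index", "stimulus_role",
    "stimulus_level", "frequency_hz", "isi_ms", "rt_ms", "correct", "x",
]
AMPLITUDES_COLUMNS = ["participant_id", "condition", "trial_index", "fz_mean_uv", "valid"]


def write_dataset(
    trials: pd.DataFrame,
    amplitudes: pd.DataFrame,
    truth: GroundTruth,
    outdir,
    epochs: pd.DataFrame | None = None,
) -> None:
    """Write trials.csv, amplitudes.csv, truth.json (and epochs.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials[TRIALS_COLUMNS].to_csv(outdir / "trials.csv", index=False)
    amplitudes[AMPLITUDES_COLUMNS].to_csv(outdir / "amplitudes.csv", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    if epochs is not None:
        epochs.to_csv(outdir / "epochs.csv", index=False)


def read_dataset(outdir) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    outdir = Path(outdir)
    trials = pd.read_csv(outdir / "trials.csv")
    missing = set(TRIALS_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trials.csv missing columns: {sorted(missing)}")
    amplitudes = pd.read_csv(outdir / "amplitudes.csv")
    missing = set(AMPLITUDES_COLUMNS) - set(amplitudes.columns)
    if missing:
        raise ValueError(f"amplitudes.csv missing columns: {sorted(missing)}")
    truth = GroundTruth.from_json((outdir / "truth.json").read_text())
    return trials, amplitudes, truth
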