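"""Slow-wave ERP feature extraction at Fz.

Works on already-epoched data: 200 samples at 250 Hz spanning -100..696 ms
around stimulus onset.  The quantities extracted are the rejection
positivity (RP) on distractor trials and the processing negativity (PN) on
target trials, both defined as the mean voltage in the 400-600 ms
post-stimulus window after baseline correction, either averaged per
condition (for the regression links) or kept single-trial (as the RP-noise
series driving trial-to-trial slope variability).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "N_SAMPLES",
    "SAMPLE_STEP_MS",
    "EPOCH_START_MS",
    "sample_times",
    "baseline_correct",
    "reject_artifact",
    "window_mean",
    "epochs_to_amplitudes",
    "condition_average",
    "rescale_noise",
]

N_SAMPLES = 200
SAMPLE_STEP_MS = 4
EPOCH_START_MS = -100

ARTIFACT_THRESHOLD_UV = 100.0
RP_WINDOW_MS = (400, 600)

SAMPLE_COLUMNS = [f"s{k:03d}" for k in range(N_SAMPLES)]


def sample_times() -> np.ndarray:
    """Time in ms of each sample: -100 + 4k for k = 0..199."""
    return EPOCH_START_MS + SAMPLE_STEP_MS * np.arange(N_SAMPLES)


def _as_epochs(samples) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    if arr.shape[-1] != N_SAMPLES:
        raise ValueError(
            f"epochs must have {N_SAMPLES} samples, got {arr.shape[-1]}"
        )
    return arr


def baseline_correct(samples) -> np.ndarray:
    """Subtract the mean of the 100 ms pre-stimulus period from every sample.

    Accepts one epoch (200,) or a stack (n, 200); returns the same shape.
    """
    arr = _as_epochs(samples)
    pre = sample_times() < 0
    corrected = arr - arr[:, pre].mean(axis=1, keepdims=True)
    return corrected.reshape(np.asarray(samples, dtype=float).shape)


def reject_artifact(samples, threshold: float = ARTIFACT_THRESHOLD_UV):
    """True where any baseline-corrected sample exceeds ``threshold`` µV in
    absolute value.  Scalar for one epoch, boolean array for a stack."""
    corrected = _as_epochs(baseline_correct(samples))
    flags = (np.abs(corrected) > threshold).any(axis=1)
    return bool(flags[0]) if np.asarray(samples).ndim == 1 else flags


def window_mean(samples, window=RP_WINDOW_MS):
    """Mean voltage in the half-open ``[start, stop)`` ms window.

    At 4 ms sampling the default 400-600 ms window covers exactly the 50
    samples with indices 125..174.
    """
    arr = _as_epochs(samples)
    t = sample_times()
    mask = (t >= window[0]) & (t < window[1])
    means = arr[:, mask].mean(axis=1)
    return float(means[0]) if np.asarray(samples).ndim == 1 else means


def epochs_to_amplitudes(epochs: pd.DataFrame) -> pd.DataFrame:
    """Reduce an epochs table to single-trial window-mean amplitudes.

    ``epochs`` columns: participant_id, condition, trial_index, s000..s199.
    Returns the amplitudes schema: participant_id, condition, trial_index,
    fz_mean_uv, valid — where ``valid`` marks artifact-free trials.
    """
    samples = epochs[SAMPLE_COLUMNS].to_numpy(dtype=float)
    corrected = baseline_correct(samples)
    out = epochs[["participant_id", "condition", "trial_index"]].copy()
    out["fz_mean_uv"] = window_mean(corrected)
    out["valid"] = ~reject_artifact(samples)
    return out


def condition_average(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Mean amplitude over valid trials per participant and condition.

    Applied to distractor-trial amplitudes this is the condition RP; applied
    to target-trial amplitudes it is the condition PN.
    """
    valid = amplitudes[amplitudes["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("no valid trials to average")
    return (
        valid.groupby(["participant_id", "condition"], sort=True)["fz_mean_uv"]
        .mean()
        .reset_index(name="mean_uv")
    )


def rescale_noise(values, mode: str = "scale") -> tuple[np.ndarray, float]:
    """Rescale single-trial amplitudes into a unit-dispersion noise series.

    ``mode='scale'`` (default) multiplies by 1/SD only; ``mode='zscore'``
    also removes the mean (any shift is absorbed by the start parameters
    during estimation, so centering is optional).  Returns the rescaled
    series and the scaling constant applied.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to estimate dispersion")
    sd = float(arr.std())  # population SD, matching unit-dispersion target
    if sd == 0:
        raise ValueError("zero dispersion: cannot rescale a constant series")
    if mode == "scale":
        return arr / sd, 1.0 / sd
    if mode == "zscore":
        return (arr - arr.mean()) / sd, 1.0 / sd
    raise ValueError(f"unknown mode {mode!r}")
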