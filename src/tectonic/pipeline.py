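"""End-to-end orchestration: simulate -> fit -> predict -> evaluate.

Each stage reads and writes plain-text artifacts (CSV/JSON) in an output
directory, always alongside the serialized run configuration and the seeds
that produced it, so any directory can be regenerated byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, synth
from .design import CONDITIONS
from .fitting import (
    ModelSpec,
    ParticipantFit,
    RegressionLink,
    backfit_dataset,
    fit_dataset,
)
from .model import StartParams

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_fit",
    "run_predict",
    "run_evaluate",
    "run_all",
    "fits_to_json",
    "fits_from_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    variant: str = "inhibition_only"
    noise_source: str = "gaussian"
    n_participants: int = 11

    @property
    def model_spec(self) -> ModelSpec:
        return ModelSpec(self.variant, self.noise_source)

    def write(self, outdir) -> None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "config.json").write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True)
        )

    @classmethod
    def read(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sub_seed(seed: int, label: str) -> int:
    """Named sub-seed fanned out from the master seed, stable across runs."""
    tag = int.from_bytes(label.encode(), "big") % (2**31)
    ss = np.random.SeedSequence([seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run_simulate(config: RunConfig, outdir) -> Path:
    """Generate and write a synthetic dataset under ``outdir``."""
    outdir = Path(outdir)
    spec = synth.DesignSpec(n_participants=config.n_participants)
    trials, amplitudes, truth = synth.make_dataset(
        _sub_seed(config.seed, "simulate"), config.noise_source, spec
    )
    synth.write_dataset(trials, amplitudes, truth, outdir)
    config.write(outdir)
    logger.info(
        "simulated %d trials for %d participants", len(trials), config.n_participants
    )
    return outdir


def fits_to_json(fits: dict[int, ParticipantFit]) -> str:
    out = {}
    for pid, fit in sorted(fits.items()):
        out[str(pid)] = {
            "variant": fit.spec.variant,
            "noise_source": fit.spec.noise_source,
            "seed": fit.seed,
            "params": {c: asdict(p) for c, p in fit.params.items()},
            "objectives": fit.objectives,
            "converged": fit.converged,
            "links": [asdict(l) for l in fit.links],
            "noise": {
                c: {"trial_index": idx.tolist(), "x": x.tolist()}
                for c, (idx, x) in fit.noise.items()
            },
        }
    return json.dumps(out, indent=2, sort_keys=True)


def fits_from_json(text: str) -> dict[int, ParticipantFit]:
    raw = json.loads(text)
    fits = {}
    for pid, d in raw.items():
        fit = ParticipantFit(
            participant_id=int(pid),
            spec=ModelSpec(d["variant"], d["noise_source"]),
            seed=d["seed"],
        )
        fit.params = {
            c: StartParams(tuple(p["tstart"]), p["tswell"], p["dstart"], p["dswell"])
            for c, p in d["params"].items()
        }
        fit.objectives = d["objectives"]
        fit.converged = d["converged"]
        fit.links = [RegressionLink(**l) for l in d["links"]]
        fit.noise = {
            c: (np.asarray(v["trial_index"]), np.asarray(v["x"]))
            for c, v in d["noise"].items()
        }
        fits[int(pid)] = fit
    return fits


def run_fit(config: RunConfig, dataset_dir, outdir) -> Path:
    """Fit the configured variant to a written dataset; emits params.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, amplitudes, _ = synth.read_dataset(dataset_dir)
    fits = fit_dataset(
        trials, config.model_spec, _sub_seed(config.seed, "fit"), amplitudes
    )
    (outdir / "params.json").write_text(fits_to_json(fits))
    config.write(outdir)
    n_bad = sum(not all(f.converged.values()) for f in fits.values())
    if n_bad:
        logger.warning("%d participant fit(s) flagged non-converged", n_bad)
    return outdir / "params.json"


def run_predict(config: RunConfig, params_path, dataset_dir, outdir) -> Path:
    """Backfit predicted RTs trial-by-trial; emits predicted_trials.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, _, _ = synth.read_dataset(dataset_dir)
    fits = fits_from_json(Path(params_path).read_text())
    predicted = backfit_dataset(fits, trials)
    predicted.to_csv(outdir / "predicted_trials.csv", index=False)
    config.write(outdir)
    return outdir / "predicted_trials.csv"


def run_evaluate(config: RunConfig, predicted_path, outdir) -> Path:
    """Vincentized report and moment tables; emits report.csv, moments.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    predicted = pd.read_csv(predicted_path)
    report = evaluation.condition_report(predicted)
    report.to_csv(outdir / "report.csv", index=False)
    obs = predicted.rename(columns={"rt_obs_ms": "rt_ms"})
    pred = predicted.rename(columns={"rt_pred_ms": "rt_ms"})
    table = evaluation.moment_difference_table(pred, obs)
    obs_m = _moment_rows(obs, "observed")
    pred_m = _moment_rows(pred, "predicted")
    pd.concat([obs_m, pred_m], ignore_index=True).to_csv(
        outdir / "moments.csv", index=False
    )
    table.to_csv(outdir / "moment_differences.csv", index=False)
    try:
        plot_densities(report, outdir / "densities.png")
    except ImportError:  # plotting is optional
        logger.info("matplotlib unavailable; skipping density plot")
    config.write(outdir)
    return outdir / "report.csv"


def plot_densities(report: pd.DataFrame, path) -> None:
    """Observed vs predicted inter-quantile density line graphs, one panel
    per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(report), figsize=(4 * len(report), 3.2),
                             squeeze=False)
    for ax, (_, row) in zip(axes[0], report.iterrows()):
        mids_obs = [(row[f"obs_q{i:02d}"] + row[f"obs_q{i + 1:02d}"]) / 2 for i in range(1, 20)]
        mids_pred = [(row[f"pred_q{i:02d}"] + row[f"pred_q{i + 1:02d}"]) / 2 for i in range(1, 20)]
        ax.plot(mids_obs, [row[f"obs_p{i:02d}"] for i in range(1, 20)], "k-", label="observed")
        ax.plot(mids_pred, [row[f"pred_p{i:02d}"] for i in range(1, 20)], "r--", label="predicted")
        ax.set_title(f"{row['condition']} (chi2={row['chi_square']:.2f})", fontsize=9)
        ax.set_xlabel("RT (ms)")
    axes[0][0].set_ylabel("density")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _moment_rows(trials: pd.DataFrame, source: str) -> pd.DataFrame:
    rows = []
    for (pid, cond), g in trials.groupby(["participant_id", "condition"]):
        m = evaluation.moments(g["rt_ms"].to_numpy())
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "source": source,
                "mean": m.mean,
                "dispersion": m.dispersion,
                "skewness": m.skewness,
                "kurtosis": m.kurtosis,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir) -> Path:
    """Full chain in one output directory."""
    outdir = Path(outdir)
    run_simulate(config, outdir / "dataset")
    params = run_fit(config, outdir / "dataset", outdir / "fit")
    predicted = run_predict(config, params, outdir / "dataset", outdir / "predict")
    run_evaluate(config, predicted, outdir / "evaluate")
    return outdir
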