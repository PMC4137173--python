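"""Vincentized distributions, chi-square fit, and distributional moments.

Runs the whole pipeline (simulate, fit, predict, evaluate) for a small
inhibition-only / Gaussian-noise configuration and prints the condition-level
goodness of fit and the moment differences.
"""

import tempfile
from pathlib import Path

import pandas as pd

from tectonic.pipeline import RunConfig, run_all

cfg = RunConfig(seed=3, variant="inhibition_only", noise_source="gaussian",
                n_participants=2)
out = Path(tempfile.mkdtemp()) / "run"
run_all(cfg, out)

report = pd.read_csv(out / "evaluate" / "report.csv")
print("chi-square (df=17) between observed and predicted group distributions:")
print(report[["condition", "chi_square"]].round(2).to_string(index=False))

diffs = pd.read_csv(out / "evaluate" / "moment_differences.csv")
print("\npredicted-minus-observed moments, averaged over participants:")
print(diffs.groupby("condition")[["mean", "dispersion", "skewness", "kurtosis"]]
      .mean().round(3))
print("\nSmall mean differences show the fit tracks central tendency;")
print("positive dispersion differences come from overpredicted slow-tail")
print("trials, where the evidence curve is flattest and small parameter")
print(f"error is amplified.  All artifacts were written under {out}.")
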