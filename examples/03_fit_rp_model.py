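"""Fit the EEG-linked RP model (7 free parameters) and backfit trial RTs.

Two participants for speed.  The two-stage procedure: six-parameter baseline
fit, per-condition distractor-start estimates, a two-parameter regression of
those estimates on condition-mean RP amplitude, baseline re-estimation with
the linked dstart, then a trial-by-trial solve for the threshold-crossing
time (the predicted RT).
"""

import numpy as np

from tectonic import fitting, synth

trials, amplitudes, truth = synth.make_dataset(
    seed=7, noise_mode="rp_noise", spec=synth.DesignSpec(n_participants=2)
)
spec = fitting.ModelSpec(variant="rp", noise_source="rp_noise")
fits = fitting.fit_dataset(trials, spec, seed=11, amplitudes=amplitudes)

for pid, fit in fits.items():
    link = fit.links[0]
    print(f"participant {pid}: link dstart = {link.intercept:.2f} + "
          f"{link.coefficient:.2f} x RP amplitude")
    print("  per-condition objective:",
          {c: round(v, 3) for c, v in fit.objectives.items()})

predicted = fitting.backfit_dataset(fits, trials)
r = np.corrcoef(predicted.rt_obs_ms, predicted.rt_pred_ms)[0, 1]
print(f"\npooled correlation generated vs predicted RTs: r = {r:.4f}")
print("A positive link coefficient means weaker RP (more salient distractors)")
print("implies weaker inhibitory drive and slower predicted responses.")
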