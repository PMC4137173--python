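"""Experimental design constants for the Garner-paradigm auditory task.

Four conditions share the same three target tones; the distractor set is a
single 1020 Hz tone at baseline and widens in frequency range across the
three filtering conditions, increasing distractor salience (dimensional
imbalance) from Filtering 1 to Filtering 3.
"""

from __future__ import annotations

CONDITIONS = ("baseline", "filtering1", "filtering2", "filtering3")
BASELINE = "baseline"
FILTERING = CONDITIONS[1:]

TARGET_HZ = (962, 1000, 1040)

# Distractor frequencies per condition; baseline uses the single middle tone.
DISTRACTOR_HZ = {
    "baseline": (1020,),
    "filtering1": (982, 1020, 1060),
    "filtering2": (954, 1020, 1090),
    "filtering3": (929, 1020, 1120),
}

TRIALS_PER_STIMULUS = 50
N_TARGET_TRIALS = 150
N_DISTRACTOR_TRIALS = 150
N_TRIALS_PER_CONDITION = 300

ISI_RANGE_MS = (1450, 1600)
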