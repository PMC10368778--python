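"""Score the rhythm of a performance against its expected timing.

Onsets are converted to proportions of the whole performance span; each
interior note's absolute proportion error is expressed relative to the
expected duration of its preceding interval.  The score is tempo-invariant:
only the *shape* of the timing counts.
"""

from keyscore import Template, TemplateGroup, rhythm_deviance, score_rhythm
from keyscore.io import KeyEvent, Performance

# four expected isochronous quarter notes -> proportions 0, 1/3, 2/3, 1
expected = [0.0, 1.0, 2.0, 3.0]

# the second note arrives late: measured proportions 0, 0.4, 2/3, 1
measured = [0.0, 0.4, 2.0 / 3.0, 1.0]
score = rhythm_deviance(measured, expected)
print("per-note deviances:", [f"{d:.3f}" for d in score.per_note_deviance])
print(f"mean deviance: {score.mean_deviance_pct:.1f}%")
# |0.4 - 1/3| / (1/3) = 0.2 for the late note, 0 for the on-time note:
# mean 10% of the expected note duration. 0% would be perfect timing.

# the full pipeline enforces eligibility: a trial with a missing or extra
# keypress cannot be aligned note-by-note and is excluded
template = Template(
    "quarters", 0, tuple(TemplateGroup((12 + i,), float(i)) for i in range(4))
)
short = Performance(
    "P01", "task1", "002", "right",
    tuple(KeyEvent(12 + i, i * 500.0, i * 500.0 + 300.0) for i in range(3)),
)
print("trial with an omitted note eligible?", score_rhythm(short, template).eligible)
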