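"""Encode a short polyphonic performance and score its melodic accuracy.

Builds a four-sound template (C4, a C-major triad, D4, E4), simulates one
performance that substitutes a wrong note, and compares the two encodings
with the Levenshtein similarity ratio.
"""

from keyscore import (
    KeyEvent,
    Performance,
    Template,
    TemplateGroup,
    build_default_keymap,
    encode_performance,
    encode_template,
    score_melodic,
)

keymap = build_default_keymap()

template = Template(
    template_id="demo",
    register_start_index=0,
    groups=(
        TemplateGroup((12,), 0.0),          # C4
        TemplateGroup((12, 16, 19), 1.0),   # C4+E4+G4 chord
        TemplateGroup((14,), 2.0),          # D4
        TemplateGroup((16,), 3.0),          # E4
    ),
)

# the player hits F4 (key 17) instead of the final E4
events = (
    KeyEvent(12, 0.0, 400.0),
    KeyEvent(12, 500.0, 900.0),
    KeyEvent(16, 505.0, 900.0),   # within the 30 ms simultaneity window
    KeyEvent(19, 512.0, 900.0),
    KeyEvent(14, 1000.0, 1400.0),
    KeyEvent(17, 1500.0, 1900.0),
)
performance = Performance("P01", "task1", "001", "right", events)

print("template encoding:   ", encode_template(template, keymap).text)
print("performance encoding:", encode_performance(events, keymap).text)

score = score_melodic(performance, template, keymap)
print(f"edit distance {score.distance}, joint length {score.len_sum}, "
      f"melodic ratio {score.ratio:.3f}")
# The single substitution costs 1 edit out of a joint length of 18
# characters (separators included), so the ratio is 1 - 1/18 = 0.944;
# 1.0 would be an errorless performance.
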