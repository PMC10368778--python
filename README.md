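# keyscore

Scoring of naturalistic keyboard performance from keypress logs, for
behavioural and motor-neuroscience studies in which participants play a
(possibly MRI-compatible) keyboard: melodic accuracy against an errorless
template, rhythmic accuracy as a proportion-deviance score, post-error
slowing under altered auditory feedback (AAF), and the surrounding device-QC
and behavioural-statistics computations.  A seeded simulator generates
template-conditioned synthetic performances so every pipeline can be
exercised and calibrated without participant data.

## The scores

**Melodic accuracy.** Each key of the instrument maps to one printable
character (the default 25-key C3–C5 register uses A–Y; an extended alphabet
of capitals, lowercase, digits and 12 punctuation marks covers 74 keys over
six octaves).  Keypresses whose onsets fall within a 30 ms simultaneity
window form a chord group whose characters are sorted alphabetically; groups
are joined by single spaces for polyphonic material.  Performance and
errorless template are encoded identically and compared with the Levenshtein
similarity ratio

```
ratio = 1 − L_distance / L_sum
```

where `L_distance` is the minimum number of single-character insertions,
omissions and substitutions (each cost 1) between the two encodings and
`L_sum` is the sum of their lengths.  1 is a perfect reproduction, 0 is no
similarity.

**Rhythmic accuracy.** Chord-collapsed onsets `t_1..t_n` and expected onsets
`e_1..e_n` are converted to proportions of their spans,
`q_i = (t_i − t_1)/(t_n − t_1)` and `p_i = (e_i − e_1)/(e_n − e_1)`; each
interior note scores `|q_i − p_i| / (p_i − p_{i−1})`, the absolute timing
error relative to the expected preceding inter-note interval, and the trial
score is 100 × the mean (0% = timing exactly proportional to the template;
the measure is tempo- and shift-invariant).  Only trials whose onset count
equals the template's group count are eligible.

**Post-error slowing.** In the AAF task a performer plays heptatonic scales
(ascending then descending, 16 keypresses) while on half the trials the
sound of one target key is shifted by ±1–2 semitones.  The behavioural
index compares the mean of the three inter-press intervals up to the target
with the mean of the three after it, per participant, via a one-way
repeated-measures ANOVA.

Supporting computations: a self-contained EM fit of the two-Gaussian
key→sound latency mixture with the fraction of events meeting the ≤25 ms
requirement; the motion-exclusion rule (≥10 volumes with framewise
displacement >2.5 mm); skewness/kurtosis ANOVA-robustness bounds (2.31/8);
within-subject one- and two-way ANOVA with partial η², Welch's t, Bonferroni
correction and ≥3 SD outlier removal.

## Worked example

```python
from keyscore import (KeyEvent, Performance, Template, TemplateGroup,
                      build_default_keymap, score_melodic)

keymap = build_default_keymap()
template = Template("demo", 0, (
    TemplateGroup((12,), 0.0),          # C4
    TemplateGroup((12, 16, 19), 1.0),   # C4+E4+G4 chord
    TemplateGroup((14,), 2.0),          # D4
    TemplateGroup((16,), 3.0),          # E4
))
events = (KeyEvent(12, 0.0, 400.0), KeyEvent(12, 500.0, 900.0),
          KeyEvent(16, 505.0, 900.0), KeyEvent(19, 512.0, 900.0),
          KeyEvent(14, 1000.0, 1400.0), KeyEvent(17, 1500.0, 1900.0))
performance = Performance("P01", "task1", "001", "right", events)
score = score_melodic(performance, template, keymap)
print(score.distance, score.len_sum, round(score.ratio, 3))
```

prints `1 18 0.944`: the template encodes to `M MQT O Q` and the performance
to `M MQT O R` (the final E4 was fumbled to F4), one substitution in a joint
length of 18 characters, hence a melodic ratio of 1 − 1/18 ≈ 0.944.

The scripts in `examples/` walk through one capability each and print what
the numbers mean: `encode_and_score_melody.py`, `rhythm_scoring.py`,
`aaf_post_error_slowing.py` (a 16-participant simulated cohort recovers an
injected 25 ms slowing: `cohort mean slowing: 25.2 ms`,
`F(1, 15) = 161.60`), and `device_latency_qc.py` (EM recovers the latency
modes: `mean 8.77 ms ... weight 81.9%`, `mean 12.69 ms ... weight 18.1%`).

A thin CLI mirrors the library:

```bash
keyscore simulate --template scale.json --seed 5 --n-trials 3 --out log.tsv
keyscore score-melodic --log log.tsv --template scale.json --no-separators --out scores.tsv
keyscore fit-latency --samples latencies.txt
keyscore qc-motion --fd fd.txt
```

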