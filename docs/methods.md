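# Methods

This note records how keyscore's scores are defined, which choices were
genuinely open, what the simulator does and does not emulate, and the
numerical conventions used throughout.  Times are milliseconds and
trial-relative; no `t = 0` convention is assumed on input — every score
re-anchors at the first event it uses.

## Encoding

Each key maps to one printable character in ascending chromatic order.  The
default map covers the 25-key C3–C5 register with capitals A–Y (key 0 = C3
= 'A', key 12 = C4 = 'M', key 24 = C5 = 'Y'); the extended alphabet draws,
in order, A–Z, a–z, 0–9 and the 12 punctuation marks `.,?!+-=/*@#$`, enough
for a 74-key, six-octave instrument.  The space character is reserved as
the group separator and can never be a key character.

Keypresses are partitioned into chord groups by a simultaneity window: an
event joins the current group iff its press time is **strictly** less than
30 ms after the group's **first** event (the anchor).  Anchoring to the
first event rather than chaining on consecutive gaps prevents a run of
30 ms-spaced presses from collapsing into one unbounded "chord"; the
chaining variant is available (`rule="pairwise"`) because the window's
reference point is a genuine ambiguity of the verbal definition.  Within a
group, characters are sorted alphabetically, which makes the encoding
invariant to the input order of simultaneous presses.  Separators are part
of the compared strings on both sides; since template and performance are
encoded by the same function, the convention contributes no edits at a
perfect match.

Grouping invariants (property-tested): the partition conserves events and
order; the encoding's non-space length equals the event count; raising the
threshold never increases the number of groups.

## Melodic score

`ratio = 1 − L_distance / L_sum`, with `L_distance` the unit-cost
Levenshtein distance between the encoded performance and the encoded
errorless template and `L_sum` the sum of the two string lengths.  The
dynamic program is implemented in the package (two-row Wagner–Fischer)
rather than delegated to a string library, because common library `ratio`
functions weight a substitution as 2 (an indel-only distance), which is a
different statistic; that convention remains available as `compat_indel2`
for sensitivity analyses.  The distance is validated in the test suite
against an exhaustive edit-script recursion on very short strings and
against edlib on all pairs up to length 5 over a four-letter alphabet, and
property-tested as a metric.

Conventions: the ratio of two empty strings is an error (no performance
against no template is meaningless); a non-empty string against an empty
one scores 0.  Note that with unit substitution cost, two equal-length
non-empty strings can never score below 0.5 — the floor of 0 is reached
only through length mismatch.  This follows from the definition and is
implemented literally.

## Rhythm score

Chord groups collapse to one onset each (the group's first press), because
polyphonic material would otherwise multiply-count a single sound
structure.  A trial is **eligible** only when its collapsed onset count
equals the template's group count; without a one-to-one note
correspondence the per-note comparison is undefined.  Eligibility is
deliberately strict — an extra accidental keypress disqualifies a trial —
which on noisy material removes a large share of trials; this is a known
limitation of the method, not of the implementation.

For an eligible trial, measured and expected onsets are mapped to
proportions of their spans (`q_i`, `p_i`, both pinned to 0 and 1 at the
endpoints) and each interior note scores `|q_i − p_i| / (p_i − p_{i−1})`:
the absolute proportion error relative to the expected **preceding**
interval.  The trial score is 100 × the mean over interior notes.

Open choices, decided as follows:

* **Denominator direction.**  The verbal definition ("the expected interval
  between the consecutive keypresses") does not say whether the interval
  before or after note i normalises its error.  The preceding interval is
  the default — the error of a note is most naturally judged against the
  duration that should have led into it — and `denominator="succeeding"` is
  available.
* **Endpoint handling.**  Endpoints contribute exactly zero by
  construction, so they are excluded from the mean; including them would
  only dilute the score toward zero by a factor `(n−2)/n`.

The score is invariant under any affine time map `t ↦ a·t + b` (a > 0),
i.e. to tempo and to clock offset — property-tested.

## AAF task and post-error slowing

Scale templates are built from the tonic's semitone step pattern (major
2-2-1-2-2-2-1, natural minor 2-1-2-2-1-2-2), ascending tonic→octave then
descending, with isochronous expected onsets.  The turnaround presses the
octave twice (end of ascent and start of descent), giving the canonical 16
keypresses; a `turnaround="single"` variant (15 presses) exists because the
turnaround convention is not inherent in "ascending and then descending".

For an altered trial with target at chord-collapsed onset ordinal k
(1-based), the default window takes **before** = intervals k−3→k−2, k−2→k−1
and k−1→k, and **after** = k→k+1, k+1→k+2 and k+2→k+3.  The interval into
the target belongs to "before" because it is completed at the target press,
before the altered sound is heard; a `strict-pre` window (k−4→k−3 …
k−2→k−1) is provided since "the three keys preceding" could also be read
that way.  Only the first altered key of a trial is analysed.  Per
participant, before/after means are averaged over altered trials and
compared with a one-way repeated-measures ANOVA (for two conditions this is
exactly the squared paired t).  `delta_ms = after − before` is invariant to
a global time shift.

## Simulator

The simulator is the package's stand-in for raw study data; its defaults
describe the study conditions it emulates:

* `base_ioi_ms = 500` (a comfortable 120 quarters/min performance tempo);
  template onsets are rescaled so their mean inter-onset interval equals it.
* Error processes per expected note, independent: omission with probability
  `omission_rate`; otherwise substitution with probability
  `substitution_rate` by a uniformly chosen key ±1 or ±2 semitones within
  the register (realistic near-miss slips, the same magnitudes as the AAF
  alterations); after each group, an extra uniform-register insertion with
  probability `insertion_rate`, midway to the next onset.  Defaults are 0 —
  noise is opted into per experiment.
* Timing: i.i.d. Gaussian onset jitter per group (`onset_jitter_sd_ms`;
  cohort experiments in the tests use 30 ms, a realistic keystroke-timing
  variability at this tempo); chord members lag their group onset by
  half-normal asynchrony truncated strictly below the 30 ms window so that
  simulated chords never split.
* AAF cohorts: the eight scales of the task (F major, F♯ minor, G major,
  G minor, A minor, B♭ major, B minor, C major, tonic keys 5, 6, 7, 7, 9,
  10, 11, 12), default 24 trials per participant (3 repetitions), exactly
  half altered; target position uniform on 5–12 (so both analysis windows
  are computable within 16 notes), alteration ±1/±2 semitones; injected
  slowing adds `slowing_delta_ms` to each of the three post-target
  intervals, so with zero jitter every altered trial's measured delta
  equals the injected value exactly.
* Latency mixture defaults: means 8.77/12.67 ms, weights 0.82/0.18 — the
  two-mode key→sound latency profile of the wireless instrument this
  package targets; component SDs are not published for that device, so the
  generator uses 0.5 ms, narrow enough to keep the modes separable and
  essentially all mass below the 25 ms perceptual bound.
* FD series: half-normal baseline around ~0.1 mm (a compliant participant)
  clipped below the spike magnitude, plus exactly `n_spikes` values above
  it.

Determinism: every generator takes a seed (or an explicit numpy Generator);
cohorts spawn one independent child stream per participant from a
`SeedSequence`, so a participant's data do not depend on cohort size.

What passing the simulation-based tests does **not** show: the simulator
has no expressive timing (rubato), no velocity dynamics, no serial error
structure (real slips cluster; these are i.i.d.), and no tempo drift.
Results on real performances can differ in exactly those respects —
in particular the rhythm-eligibility fraction of real polyphonic playing is
far lower than i.i.d. error models suggest.

## Device QC and statistics

* **Latency mixture fit**: univariate Gaussian-mixture EM in log space,
  quantile-based initial means plus jittered random restarts (best
  likelihood kept), variance floor 1e-6, convergence when the
  log-likelihood gain falls below a relative tolerance (default 1e-10,
  max 500 iterations); monotone non-decrease of the log-likelihood is
  asserted at every iteration.  Non-convergence returns best-so-far
  parameters flagged `converged=False`.  Components are reported in
  ascending mean order.  The fit is cross-checked against
  scikit-learn's GaussianMixture in the tests.
* **Latency bound**: the fraction of samples **≤** the bound (inclusive;
  default 25 ms).
* **Motion exclusion**: FD strictly greater than the threshold (default
  2.5 mm, one voxel dimension) counts a volume; ten or more counted
  volumes (inclusive) exclude the participant.
* **Robustness bounds**: bias-corrected sample skewness and kurtosis;
  the kurtosis bound of 8 is applied to the raw (Pearson) form, under
  which a normal distribution scores 3 and the robustness region
  |skew| ≤ 2.31, kurtosis ≤ 8 contains the reference shape (−1.56, 2.3);
  the excess form is reported alongside since the convention behind the
  bound is not standardised.
* **RM-ANOVA**: classical fully-within-subject sums-of-squares
  decomposition, each effect tested against its interaction with subjects;
  partial η² = SS_eff/(SS_eff+SS_err) = F·df1/(F·df1+df2).  Degrees of
  freedom are uncorrected by default (matching how such designs are
  commonly reported); a Greenhouse–Geisser correction is available for the
  one-way case.  Incomplete designs raise — no imputation.  Verified
  against pingouin and a hand-worked 2×2 dataset in the tests.
* **Two-sample t**: Welch (unequal variances, fractional df) with a 95% CI
  of the mean difference and pooled-SD Cohen's d.  Two zero-variance
  samples with equal means return t = 0, p = 1 by convention.
* **Outlier removal**: single pass, group mean and SD estimated once,
  values ≥ 3 SD from their group mean removed; no iterative re-trimming,
  so one call is idempotent by construction.
* **Bonferroni**: `min(1, m·p)`.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` size their simulations as
follows: degradation monotonicity uses 200 simulated trials per error rate;
AAF recovery uses cohorts of 16 participants × 6 trials (3 altered), 200
cohorts per injected delta in the tests and 50 in the acceptance script;
the ANOVA type-I-error check uses 1000 null cohorts; mixture recovery uses
10⁴ latency draws.  These sizes give Monte-Carlo standard errors well below
the effects being checked while keeping the whole suite quick to run.

## Known limitations

* The eligibility rule discards every trial with a note-count mismatch; no
  partial-credit alignment is attempted (a refinement would require an
  explicit note-to-note alignment model).
* The melodic ratio treats all substitutions equally; pitch distance and
  enharmonic spelling are out of scope.
* The log dialect is this package's own TSV; vendor presentation-software
  logs need conversion.
* FD is consumed, not computed from motion parameters.
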