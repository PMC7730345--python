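# Methods

## The measurement model

### Score as a metrical time scale

A metronome at `bpm` beats per minute makes musical time advance in beats of
`60/bpm` seconds.  For simple quarter-note stimuli the score can be read as
a visual graph of that time: each note symbol marks one beat, and positions
between symbols correspond to fractional beats.  `score_model` implements
this as a piecewise-linear map through `(beat, x_px)` anchor pairs —
`x_to_beat` and its exact inverse `beat_to_x`.  Beyond the outermost anchors
the adjacent segment's slope is extended, so fixations slightly left of the
first note or right of the last still receive a beat position.  The map is
strictly monotone by construction; all span arithmetic uses the horizontal
axis only.

Two anchor dialects are supported, reflecting two ways real stimuli are
engraved: `stem_midpoint` (anchors at note stems, AOI cuts midway between
stems) and `head_midpoint` (anchors at note-head centers, cuts midway
between heads).  AOIs are half-open intervals `[left, right)` with boundary
ties going right — a deterministic convention that keeps the AOI row an
exact partition of the analyzed region.  Vertically, fixations count as
reading the staff when they fall within the staff band extended by
`aoi_vertical_margin` (default 35 px, roughly 9.5 mm on a 23-inch 1080p
display at 65 cm); the same default is used for both dialects since no
principled alternative is available for the second.

### Metronome synchronization

The click phase is estimated from synchronization timestamps produced on
metronome clicks (e.g. experimenter key presses): the residues of the
timestamps modulo the beat period all estimate the click offset, and their
**circular median** — the residue minimizing summed circular distance on the
period circle — is the phase reference.  Away from the wrap boundary this
equals the plain median of the fractional parts; at the boundary (clicks
near a whole period) the plain median is misleading while the circular
median is not, which is why the circular version is used.  A residue
dispersion above a quarter period is logged as a synchronization-quality
warning; no correction is attempted.  The performance start is snapped to
the nearest click, and the metrical time of any instant is
`(t − start) / period` beats.  For sessions with a pre-programmed tempo
change, each tempo segment carries its own spec; the phase for a later
segment can be estimated from the same timestamps modulo the new period.

### Spans and screening

For each note the **first fixation** inside its AOI is paired with its raw
predecessor in the full fixation stream (the saccade launch site, whether or
not that fixation hit any AOI).  The ETS uses the fixation's actual landing
position, not the AOI center.  The incoming saccade is converted to beats
through the same anchor map, so non-uniform spacing (e.g. wider gaps across
bar lines) is handled segment-locally instead of through a global
pixels-per-beat ratio.

Three screening rules flag records, first match wins:

1. negative ETS (the eye behind the metrical cursor);
2. regressive incoming saccade (strictly leftward; zero displacement
   passes, since the rule targets leftward movement);
3. incoming saccade longer than ETS + 2 beats (discards long return sweeps
   after glances back to already-played material).

Flagged records are left out of analysis, never replaced by the next
fixation on the AOI.  A first fixation with no predecessor keeps its ETS
with the saccade undefined (NaN); it drops out of any analysis requiring the
saccade.  The rules are idempotent and order-stable.

Two baseline spans are computed when a performance log is supplied: the
single-item lag (`performance onset − fixation onset`, seconds) and the
forward-projective span (beats between the active fixation's position and
the metrical cursor at a probe time).  With a mechanical performance exactly
on the click grid and noise-free landings, `ETS × beat period` equals the
single-item lag for every measured note — an identity the test suite
verifies to 1e-9 — while the two measures diverge as soon as landings are
noisy or performances are human.

## The simulator

`simulate` provides the test bed: everything the measurement chain consumes
can be generated with known ground truth.

**Stimuli.**  Melodies are sampled as walks on the diatonic degree lattice
with a dynamic program that guarantees the construction constraints exactly.
The `exp1` dialect produces five-bar melodies (16 quarters + closing whole
note on the mid-register third, degrees 1–5, uniform 15 mm ≈ 57 px anchor
spacing) in three conditions: `stepwise` (no interval above a step), and
`barline` / `midbar`, which insert one perfect fourth and one perfect fifth
landing on the downbeats of bars 3 and 4 or two beats after them.  The six
notes from the second half of bar 2 through bar 3 carry the `analysis` tag.
The `exp2` dialect produces long quarter-note melodies on four staves of six
bars (bars per staff configurable), one minor-sixth skip per staff in
staff-bars 3–5 whose chromatically altered target is the last note of its
bar; the lattice walk's state includes the direction of the incoming step so
that the skip provably reverses the preceding motion and the post-skip step
turns back to fill the gap.  A matched stepwise control bar per staff is
tagged for analysis.

**Performances.**  Mechanical performances place note onsets exactly on the
click grid; the jittered variant adds Gaussian timing noise and reduces to
the mechanical one at zero jitter.

**Scanpaths.**  For each note `n` at beat `b_n` (skipped with probability
`p_skip`), a look-ahead is drawn

```
L_n ~ Gamma(shape k, mean μ · a_n · m_tempo · f_participant + expertise offset scaling)
```

with `a_n` the attraction multiplier at tagged notes (and, via
`attraction_window`, at notes shortly before them), `m_tempo` a per-tempo
multiplier, and `f_participant` a lognormal participant factor.  The
fixation onset is placed so that metrical time at onset is `b_n − L_n`; the
landing is `b_n + ε`, `ε ~ N(0, σ)`, mapped to pixels through the layout.
Onsets are clipped to be strictly increasing and no earlier than the
stimulus display onset; clipped notes are flagged in the returned truth
table, because their measured span no longer equals the generated one.
Durations fill the inter-onset gaps.  The random stream consumes a fixed
number of draws per note regardless of skipping or attraction, so changing
the attraction multiplier perturbs only the tagged notes under a common
seed.  Each (participant, trial) has its own stream derived from the study
seed, making any trial independently reproducible.

Because the measurement chain inverts this construction, the measured ETS
at every non-clipped, non-skipped note equals `L_n + ε` exactly (the suite
checks 1e-6 over >10⁴ notes), and consecutive spans obey the chain identity
`ETS(F) = ETS(F_prev) − Δbeats + saccade`.

**Defaults** (chosen once as a realistic portrait of competent readers at a
comfortable tempo): μ = 2.0 beats, k = 4 (clearly right-skewed, sample
skewness ≈ 1–2), σ = 0.1 beats, p_skip = 0.02, participant lognormal sd
0.15, tempo multiplier 1.0 at 60 bpm and 1.15 at 100 bpm (spans grow
sub-proportionally with tempo), attraction multiplier 1 (null), no
regressions.  An optional regression-injection rate produces rightward
off-staff excursions solely to exercise screening rule 2.

**What the simulator does not emulate:** oculomotor realism (main-sequence
velocities, fixation-duration distributions, vertical landing scatter),
refixations and genuine regressive reading, performance errors, and any
dependence of look-ahead on musical content beyond the tagged-note
multiplier.  Passing tests therefore demonstrate the correctness and
calibration of the *measurement and analysis chain* under a plausible
generative model — not the behavior of human readers.

## Statistical analysis

Span measurements are correlated within participants and right-skewed, so
the condition analysis is a marginal (population-average) model estimated by
GEE: gamma variance function, inverse link (the response stays on its
natural scale; no log transform), exchangeable working correlation,
cluster-robust sandwich covariance, clustered by participant.  Estimation is
statsmodels' GEE; the gamma dispersion is reported from Pearson moments for
transparency.

**Per-term tests.**  Each term's robust Wald χ² is reported.  With m
clusters and a q-degree constraint, referring the statistic to χ²_q is
severely anticonservative when q is not small relative to m (for the 10-df
condition-by-note interaction at m = 30, simulation shows ~38% rejection at
a nominal 5%).  P-values therefore use the Hotelling-type reference

```
W · (m − q) / (q · (m − 1))  ~  F(q, m − q),
```

which is the exact reference for a Hotelling T² statistic with an
m-sample covariance estimate and converges to the χ² reference as m grows.
Under the simulator's null this holds the interaction test's level within
its binomial band at m = 30 while retaining >80% power for a 1.3-fold local
attraction effect.  The asymptotic χ² p-value is reported alongside
(`p_asymptotic`) for comparison with software that uses it.

**Model selection.**  For designs with an expertise factor, interaction
terms involving expertise whose Wald p ≥ α (default .05) are discarded and
the model refit once; both fits are returned.  Main effects are never
dropped.

**Post hoc contrasts.**  Estimated marginal means are formed on the link
scale by averaging design rows over the levels of the remaining factors
(equal weights) and back-transformed; pairwise differences across one
factor's levels at each level of another are therefore on the response
scale (beats).  Standard errors come from the delta method with the robust
covariance.  Multiplicity is controlled per comparison family (all pairwise
condition contrasts within one note) by the single-step equicoordinate
multivariate-normal adjustment using the estimated correlation of the
contrast statistics — the Tukey-style adjustment appropriate for
z-statistics; with a single pair it reduces to the unadjusted p-value.

**Association.**  The ETS–saccade association is the Spearman rank
correlation with average ranks for ties, computed on records surviving the
screening rules.  Because the incoming saccade is arithmetically a component
of the ETS (chain identity), simulated studies show a moderate positive rank
correlation even with no attraction effect; this mirrors what the measure
implies and is not evidence of anything beyond it.

## Numerical and design choices

* Coordinates follow the screen convention (x right, y down); beats are
  continuous floats, 0-based at the performance start; bar and position
  labels are 1-based and purely descriptive.
* `beat_to_x ∘ x_to_beat` is an identity to 1e-9 over the anchor hull; with
  uniform anchors the map is affine to 1e-12.
* AOI boundary ties go right; exclusion rules apply in the fixed order
  1→2→3 with first match winning (rule precedence is a convention; the
  screening counts per rule depend on it only for records matching several
  rules).
* The GEE estimation tolerance (1e-6) and iteration cap (60) are exposed;
  a constant response is resolved analytically at the link-transformed
  constant (zero-dispersion boundary) rather than iterated.
* Times in input files are milliseconds (eye-tracker convention) and
  converted to seconds internally; spans are reported in beats.
* α = .05 throughout.

## Problem sizes used by the validation suite

The simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the tested tolerance: 100 trials for the
mechanical-performance equivalence (exact identity, 1e-9), ~10,200 generated
notes for round-trip recovery (1e-6), a full default study for the chain
identity (1e-9), and 200 null / 100 effect replicates of a 30-participant,
12-trial study for the calibration of the interaction test.

## Known limitations

* The ETS presumes an isochronous quarter-note score read as a time scale;
  mixed note values or rubato would need a generalized beat↔pixel map and a
  non-metronomic definition of the cursor.
* Fixation detection is consumed as given; detector settings shift what
  counts as a "first fixation".
* The vertical axis is only a band filter; pitch-direction landing effects
  are out of scope.
* The small-sample F reference calibrates the multi-degree Wald test but is
  itself an approximation; with very few clusters (m ≤ q) it falls back to
  the χ² reference, which should not be trusted there.
* Multi-staff stimuli are handled per staff line; return sweeps between
  staves are not modeled and their fixations are simply assigned to
  whichever staff band they land in.
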