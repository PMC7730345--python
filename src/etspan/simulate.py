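"""Synthetic stimuli, performances, and scanpaths for the span pipeline.

The generator emulates the two stimulus families used in temporally
controlled sight-reading studies of "looking ahead":

* dialect ``exp1`` — five-bar quarter-note melodies on the first five
  diatonic degrees, sixteen quarters plus a closing whole note, with two
  larger intervals (a perfect fourth and a perfect fifth) placed either at
  the bar lines surrounding bar 3 (``barline``), two beats after them
  (``midbar``), or absent (``stepwise``);
* dialect ``exp2`` — long quarter-note melodies laid out on several staves,
  each staff containing exactly one minor-sixth skip whose chromatically
  altered target is the last note of its bar (bars 3–5 of the staff), with
  stepwise motion reversing into the skip and filling the gap after it.

Scanpaths are generated from a simple look-ahead model: the first fixation
on note *n* occurs when metrical time stands ``L_n`` beats before the note,
with ``L_n`` gamma-distributed (right-skewed, like empirical ETS
populations) around a mean that is scaled multiplicatively at attraction
targets; the landing position gets Gaussian noise on the beat axis; notes
are occasionally skipped.  Because the measurement chain inverts exactly
this construction, the generated look-ahead plus landing noise is
recoverable note by note, which is the test bed for the whole package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .score_model import (
    Fixation,
    NoteEvent,
    ScoreLayout,
    aoi_boundaries_from_notes,
    beat_to_x,
)
from .spans import SpanRecord, compute_span_records
from .sync import TempoSpec, snap_to_click

__all__ = [
    "SimConfig",
    "MelodySpec",
    "SimulationError",
    "generate_melody",
    "layout_for_notes",
    "layouts_by_staff",
    "mechanical_performance",
    "jittered_performance",
    "simulate_scanpath",
    "simulate_trial",
    "simulate_study",
    "note_degree",
]

logger = logging.getLogger(__name__)

# Pixel defaults: 23" 1920-px-wide screen, ~0.265 mm/px.  15 mm stem spacing
# (exp1) ~ 57 px; 11 mm within-bar / 15 mm cross-bar head spacing (exp2)
# ~ 42 / 57 px.  Staff band ~ 9 mm ~ 34 px.
EXP1_SPACING_PX = 57.0
EXP2_WITHIN_BAR_PX = 42.0
EXP2_CROSS_BAR_PX = 57.0
STAFF_Y_TOP = 500.0
STAFF_Y_BOTTOM = 534.0
X_ORIGIN_PX = 160.0


class SimulationError(RuntimeError):
    """Raised when a melody specification admits no valid note sequence."""


@dataclass
class SimConfig:
    """Generative parameters of the scanpath model.

    Defaults describe a competent reader at a comfortable tempo: mean
    look-ahead ``lookahead_mean_beats`` of 2.0 beats with gamma shape 4
    (clearly right-skewed), landing noise of 0.1 beats, 2% note skipping,
    multiplicative within-reader heterogeneity of 0.15 (log scale), and a
    1.15 look-ahead multiplier at 100 bpm (spans grow sub-proportionally
    with tempo).  ``attraction_multiplier`` = 1 is the null: no local
    effect at tagged notes.
    """

    seed: int = 0
    n_participants: int = 30
    trials_per_tempo: int = 6
    tempi_bpm: Tuple[float, ...] = (60.0, 100.0)
    lookahead_mean_beats: float = 2.0
    lookahead_shape: float = 4.0
    attraction_multiplier: float = 1.0
    attraction_window: int = 0
    attraction_tag: str = "skip_target"
    landing_sd_beats: float = 0.1
    p_skip: float = 0.02
    expertise_offset_beats: float = 0.0
    participant_sd: float = 0.15
    tempo_multipliers: Dict[float, float] = field(
        default_factory=lambda: {60.0: 1.0, 100.0: 1.15}
    )
    regression_rate: float = 0.0
    lead_in_beats: float = 2.0
    performance_jitter_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.lookahead_mean_beats > 0:
            raise ValueError("lookahead_mean_beats must be > 0")
        if not self.lookahead_shape > 0:
            raise ValueError("lookahead_shape must be > 0")
        if not self.attraction_multiplier > 0:
            raise ValueError("attraction_multiplier must be > 0")
        if self.landing_sd_beats < 0:
            raise ValueError("landing_sd_beats must be >= 0")
        if not 0 <= self.p_skip < 1:
            raise ValueError("p_skip must be in [0, 1)")


@dataclass
class MelodySpec:
    """Construction rules for one stimulus melody."""

    experiment_dialect: str = "exp1"  # exp1 | exp2
    condition: str = "stepwise"  # stepwise | barline | midbar | skip
    key: str = "C"
    inversion: bool = False
    n_staves: int = 4  # exp2 only
    bars_per_staff: int = 6  # exp2 only
    first_target_bar: int = 3  # exp2 only: 3 or 4

    def __post_init__(self) -> None:
        if self.experiment_dialect not in ("exp1", "exp2"):
            raise ValueError(f"unknown dialect {self.experiment_dialect!r}")
        if self.experiment_dialect == "exp1" and self.condition not in (
            "stepwise",
            "barline",
            "midbar",
        ):
            raise ValueError(f"exp1 condition must be stepwise/barline/midbar, got {self.condition!r}")
        if self.experiment_dialect == "exp2":
            if self.condition != "skip":
                raise ValueError("exp2 melodies use condition='skip'")
            if self.first_target_bar not in (3, 4):
                raise ValueError("first_target_bar must be 3 or 4")
            if self.bars_per_staff < 5:
                raise ValueError("need at least 5 bars per staff to place targets in bars 3-5")


def note_degree(note: NoteEvent) -> int:
    """Diatonic scale degree encoded in the note's tags."""
    for t in note.tags:
        if t.startswith("degree:"):
            return int(t.split(":", 1)[1])
    raise KeyError(f"note {note.note_id} carries no degree tag")


# --------------------------------------------------------------------------
# melodic-contour sampling: weighted paths through the diatonic degree lattice

def _sample_degrees(
    n_notes: int,
    start: int,
    ends: Sequence[int],
    allowed: Sequence[Sequence[Tuple[int, float]]],
    lo: int,
    hi: int,
    rng: np.random.Generator,
) -> List[int]:
    """Sample a degree sequence with per-transition step options.

    ``allowed[i]`` lists ``(step, weight)`` options for the transition from
    note i to note i+1.  A weighted count of completions is computed by
    dynamic programming from the end, then the path is sampled forward in
    proportion to weight x completion mass, guaranteeing feasibility.
    """
    n_states = hi - lo + 1
    mass = np.zeros((n_notes, n_states))
    for e in ends:
        mass[-1][e - lo] = 1.0
    for i in range(n_notes - 2, -1, -1):
        for d in range(lo, hi + 1):
            tot = 0.0
            for step, w in allowed[i]:
                nd = d + step
                if lo <= nd <= hi:
                    tot += w * mass[i + 1][nd - lo]
            mass[i][d - lo] = tot
    if mass[0][start - lo] <= 0:
        raise SimulationError("melody constraints admit no valid note sequence")
    path = [start]
    d = start
    for i in range(n_notes - 1):
        opts, probs = [], []
        for step, w in allowed[i]:
            nd = d + step
            if lo <= nd <= hi and mass[i + 1][nd - lo] > 0:
                opts.append(nd)
                probs.append(w * mass[i + 1][nd - lo])
        probs = np.asarray(probs) / sum(probs)
        d = int(opts[rng.choice(len(opts), p=probs)])
        path.append(d)
    return path


def _exp1_notes(spec: MelodySpec, rng: np.random.Generator) -> List[NoteEvent]:
    n_notes = 17  # 16 quarters + closing whole note
    start = 5 if spec.inversion else 1  # G4 vs C4, degrees 1..5 of C major
    end = 3  # E4 whole note
    step_opts = [(-1, 1.0), (1, 1.0), (0, 0.15)]
    if spec.condition == "stepwise":
        skip_targets: List[int] = []
    elif spec.condition == "barline":
        skip_targets = [8, 12]  # downbeats of bars 3 and 4
    else:  # midbar
        skip_targets = [10, 14]  # two quarter-note beats after those bar lines
    # one skip is a perfect fourth (3 steps), the other a perfect fifth (4)
    sizes = [3, 4] if rng.random() < 0.5 else [4, 3]
    allowed: List[List[Tuple[int, float]]] = []
    for i in range(n_notes - 1):
        tgt = i + 1
        if tgt in skip_targets:
            size = sizes[skip_targets.index(tgt)]
            allowed.append([(-size, 1.0), (size, 1.0)])
        else:
            allowed.append(list(step_opts))
    degrees = _sample_degrees(n_notes, start, [end], allowed, 1, 5, rng)
    notes = []
    for i, d in enumerate(degrees):
        tags = {f"degree:{d}"}
        if 6 <= i <= 11:  # second half of bar 2 + bar 3: the analyzed region
            tags.add("analysis")
        if i in skip_targets:
            tags.add("skip_target")
        if i + 1 in skip_targets:
            tags.add("pre_skip")
        notes.append(
            NoteEvent(
                note_id=f"n{i:02d}",
                beat_onset=float(i),
                bar_index=i // 4 + 1,
                pos_in_bar=i % 4 + 1,
                x_anchor=X_ORIGIN_PX + EXP1_SPACING_PX * i,
                tags=frozenset(tags),
            )
        )
    return notes


def _exp2_target_bars(spec: MelodySpec, rng: np.random.Generator) -> List[int]:
    first = spec.first_target_bar
    middles = [4, 5] if first == 3 else [3, 5]
    if rng.random() < 0.5:
        middles = middles[::-1]
    bars = [first] + middles + [first]
    return bars[: spec.n_staves] if spec.n_staves <= 4 else (
        bars + [first] * (spec.n_staves - 4)
    )


# for a target in staff bar 3 / 4 / 5 the stepwise control bar is 5 / 2 / 3
_EXP2_CONTROL_BAR = {3: 5, 4: 2, 5: 3}


def _exp2_degrees(
    n_notes: int,
    start: int,
    ends: Sequence[int],
    target_idx: Sequence[int],
    lo: int,
    hi: int,
    rng: np.random.Generator,
) -> List[int]:
    """Sample exp2 degree contours with a sign-aware lattice walk.

    The dynamic-programming state is (degree, sign of the incoming step), so
    two melodic constraints can be enforced exactly: the minor-sixth skip
    reverses the preceding stepwise motion, and the step after the skip
    turns back stepwise to fill the gap.
    """
    targets = set(target_idx)

    def options(i: int, s: int) -> List[Tuple[int, float]]:
        if (i + 1) in targets:
            # the skip: 5 diatonic steps, opposing the motion it interrupts
            return [(step, 1.0) for step in (-5, 5) if s == 0 or step * s < 0]
        if i in targets:
            return [(-s, 1.0)]  # fill the gap stepwise
        return [(-1, 1.0), (1, 1.0), (-2, 0.03), (2, 0.03)]  # no repeats

    n_deg = hi - lo + 1
    # mass[i][d - lo][s] with s index 0/1/2 -> sign -1/+1/0 (0 only at i=0)
    mass = np.zeros((n_notes, n_deg, 3))
    for e in ends:
        mass[-1, e - lo, 0] = mass[-1, e - lo, 1] = 1.0
    sidx = {-1: 0, 1: 1, 0: 2}
    for i in range(n_notes - 2, -1, -1):
        for d in range(lo, hi + 1):
            for s in ((0,) if i == 0 else (-1, 1)):
                tot = 0.0
                for step, w in options(i, s):
                    nd = d + step
                    if lo <= nd <= hi:
                        tot += w * mass[i + 1, nd - lo, sidx[1 if step > 0 else -1]]
                mass[i, d - lo, sidx[s]] = tot
    if mass[0, start - lo, sidx[0]] <= 0:
        raise SimulationError("melody constraints admit no valid note sequence")
    degrees = [start]
    d, s = start, 0
    for i in range(n_notes - 1):
        opts, probs = [], []
        for step, w in options(i, s):
            nd = d + step
            ns = 1 if step > 0 else -1
            if lo <= nd <= hi and mass[i + 1, nd - lo, sidx[ns]] > 0:
                opts.append((nd, ns))
                probs.append(w * mass[i + 1, nd - lo, sidx[ns]])
        probs = np.asarray(probs) / sum(probs)
        d, s = opts[rng.choice(len(opts), p=probs)]
        degrees.append(d)
    return degrees


def _exp2_notes(spec: MelodySpec, rng: np.random.Generator) -> List[NoteEvent]:
    npb = 4  # quarter notes per 4/4 bar
    notes_per_staff = spec.bars_per_staff * npb
    n_notes = spec.n_staves * notes_per_staff
    lo, hi = 1, 8  # one diatonic octave, tonic at both ends
    target_bars = _exp2_target_bars(spec, rng)
    target_idx = [
        s * notes_per_staff + (bar - 1) * npb + (npb - 1)
        for s, bar in enumerate(target_bars)
    ]  # last note of its bar
    degrees = _exp2_degrees(n_notes, lo, [lo, hi], target_idx, lo, hi, rng)
    notes = []
    for i, d in enumerate(degrees):
        staff = i // notes_per_staff
        staff_bar = (i % notes_per_staff) // npb + 1
        tags = {f"degree:{d}", f"staff:{staff}"}
        if staff_bar == target_bars[staff]:
            tags.update({"analysis", "skip_bar"})
        if staff_bar == _EXP2_CONTROL_BAR[target_bars[staff]]:
            tags.update({"analysis", "stepwise_bar", "stepwise_control"})
        if i in target_idx:
            tags.update({"skip_target", "chromatic"})
        if i + 1 in target_idx:
            tags.add("pre_skip")
        # cross-bar gaps are wider than within-bar gaps; x resets per staff
        j = i % notes_per_staff
        x = (
            X_ORIGIN_PX
            + EXP2_WITHIN_BAR_PX * (j - j // npb)
            + EXP2_CROSS_BAR_PX * (j // npb)
        )
        notes.append(
            NoteEvent(
                note_id=f"s{staff}n{i:03d}",
                beat_onset=float(i),
                bar_index=i // npb + 1,
                pos_in_bar=i % npb + 1,
                x_anchor=x,
                tags=frozenset(tags),
            )
        )
    return notes


def generate_melody(spec: MelodySpec, seed: int) -> List[NoteEvent]:
    """Generate a stimulus note table following the dialect's construction
    rules.  Deterministic given ``seed``."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 1])
    if spec.experiment_dialect == "exp1":
        return _exp1_notes(spec, rng)
    return _exp2_notes(spec, rng)


# --------------------------------------------------------------------------
# layout and performances

def layout_for_notes(
    notes: Sequence[NoteEvent],
    dialect: str = "stem_midpoint",
    staff_y_top: float = STAFF_Y_TOP,
    staff_y_bottom: float = STAFF_Y_BOTTOM,
    aoi_vertical_margin: float = 35.0,
) -> ScoreLayout:
    """Build the beat<->pixel layout for one staff line of notes."""
    return ScoreLayout(
        anchors=[(n.beat_onset, n.x_anchor) for n in notes],
        staff_y_top=staff_y_top,
        staff_y_bottom=staff_y_bottom,
        aoi_vertical_margin=aoi_vertical_margin,
        aoi_boundaries=aoi_boundaries_from_notes(notes),
        dialect=dialect,
    )


def layouts_by_staff(
    notes: Sequence[NoteEvent], **kwargs
) -> List[Tuple[List[NoteEvent], ScoreLayout]]:
    """Group a multi-staff note table into per-staff (notes, layout) pairs."""
    staves: Dict[int, List[NoteEvent]] = {}
    for n in notes:
        s = 0
        for t in n.tags:
            if t.startswith("staff:"):
                s = int(t.split(":", 1)[1])
        staves.setdefault(s, []).append(n)
    return [
        (staves[s], layout_for_notes(staves[s], **kwargs)) for s in sorted(staves)
    ]


def mechanical_performance(
    notes: Sequence[NoteEvent], tempo: TempoSpec
) -> Dict[str, float]:
    """Note onsets of a performance perfectly synchronized to the metronome."""
    start = snap_to_click(tempo.performance_start_s, tempo)
    return {n.note_id: start + n.beat_onset * tempo.beat_period_s for n in notes}


def jittered_performance(
    notes: Sequence[NoteEvent],
    tempo: TempoSpec,
    jitter_sd_s: float,
    rng: np.random.Generator,
) -> Dict[str, float]:
    """Humanly imprecise performance: mechanical onsets plus Gaussian jitter.
    Zero jitter reduces exactly to the mechanical performance."""
    mech = mechanical_performance(notes, tempo)
    if jitter_sd_s == 0:
        return mech
    return {k: v + rng.normal(0.0, jitter_sd_s) for k, v in mech.items()}


# --------------------------------------------------------------------------
# scanpath generation

def _attracted_indices(
    notes: Sequence[NoteEvent], tag: str, window: int
) -> set:
    idx = {i for i, n in enumerate(notes) if n.has_tag(tag)}
    out = set()
    for i in idx:
        for w in range(window + 1):
            if i - w >= 0:
                out.add(i - w)
    return out


def simulate_scanpath(
    notes: Sequence[NoteEvent],
    layout: ScoreLayout,
    tempo: TempoSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
    participant_factor: float = 1.0,
) -> Tuple[List[Fixation], pd.DataFrame]:
    """Generate one trial's fixation sequence plus its ground truth.

    For each note (unless skipped) a look-ahead ``L`` is drawn from a gamma
    distribution whose mean is the baseline mean times the attraction,
    tempo, and participant multipliers (plus the expertise offset); the
    fixation onset is placed so that metrical time at onset is the note's
    beat minus ``L``; the landing is the note's beat plus Gaussian noise,
    mapped to pixels through the layout.  Onsets are clipped to be strictly
    increasing and not earlier than the stimulus display onset; clipped
    notes are flagged in the truth table because their measured span no
    longer equals the generated one.  Fixation durations fill the
    inter-onset gaps.  The random stream consumes the same number of draws
    per note whether or not the note is skipped or attracted, so with a
    null attraction multiplier tagged and untagged notes see identical
    noise.
    """
    period = tempo.beat_period_s
    start = snap_to_click(tempo.performance_start_s, tempo)
    display_onset = start - cfg.lead_in_beats * period
    tempo_mult = cfg.tempo_multipliers.get(float(tempo.bpm), 1.0)
    attracted = _attracted_indices(notes, cfg.attraction_tag, cfg.attraction_window)
    y_mid = (layout.staff_y_top + layout.staff_y_bottom) / 2.0

    events: List[Tuple[float, float, float]] = []  # (onset, x, y)
    truth_rows = []
    prev_onset = -math.inf
    min_gap = 1e-3
    base_mean = cfg.lookahead_mean_beats + cfg.expertise_offset_beats
    if base_mean <= 0:
        raise ValueError("lookahead mean plus expertise offset must stay positive")
    for i, note in enumerate(notes):
        # fixed draw count per note keeps streams comparable across configs
        u_skip = rng.random()
        g = rng.gamma(cfg.lookahead_shape, 1.0 / cfg.lookahead_shape)
        eps = rng.normal(0.0, 1.0)
        u_reg = rng.random()
        a = cfg.attraction_multiplier if i in attracted else 1.0
        mean = base_mean * a * tempo_mult * participant_factor
        lookahead = mean if math.isinf(cfg.lookahead_shape) else mean * g
        eps_beats = eps * cfg.landing_sd_beats
        skipped = u_skip < cfg.p_skip
        if skipped:
            truth_rows.append(
                dict(note_id=note.note_id, beat=note.beat_onset, lookahead_beats=np.nan,
                     landing_eps_beats=np.nan, landing_beat=np.nan, onset_s=np.nan,
                     skipped=True, clipped=False, attracted=i in attracted)
            )
            continue
        onset = start + (note.beat_onset - lookahead) * period
        clipped = False
        if onset < display_onset:
            onset = display_onset
            clipped = True
            logger.debug("look-ahead truncated at display onset for %s", note.note_id)
        if onset <= prev_onset:
            onset = prev_onset + min_gap
            clipped = True
        landing_beat = note.beat_onset + eps_beats
        x = float(beat_to_x(layout, landing_beat))
        if cfg.regression_rate > 0 and u_reg < cfg.regression_rate and events:
            # rightward excursion off the staff band just before this first
            # fixation: its incoming saccade becomes regressive (rule ii food)
            exc_onset = (prev_onset + onset) / 2.0
            if exc_onset > prev_onset + min_gap / 2 and exc_onset < onset:
                exc_x = float(beat_to_x(layout, landing_beat + 2.0))
                events.append((exc_onset, exc_x, layout.staff_y_bottom
                               + layout.aoi_vertical_margin + 50.0))
        events.append((onset, x, y_mid))
        prev_onset = onset
        truth_rows.append(
            dict(note_id=note.note_id, beat=note.beat_onset, lookahead_beats=lookahead,
                 landing_eps_beats=eps_beats, landing_beat=landing_beat, onset_s=onset,
                 skipped=False, clipped=clipped, attracted=i in attracted)
        )
    events.sort(key=lambda e: e[0])
    fixations = []
    for j, (onset, x, y) in enumerate(events):
        dur = (events[j + 1][0] - onset) if j + 1 < len(events) else period
        fixations.append(Fixation(onset_s=onset, duration_s=max(dur, min_gap / 2), x_px=x, y_px=y))
    return fixations, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# study-level generation

_EXP1_CONDITIONS = ("stepwise", "barline", "midbar")


def _study_melodies(cfg: SimConfig, n_variants: int) -> Dict[Tuple[str, int], List[NoteEvent]]:
    """The fixed stimulus set of a study: one melody per (condition, variant),
    inversions alternating across variants."""
    out = {}
    for ci, cond in enumerate(_EXP1_CONDITIONS):
        for v in range(n_variants):
            spec = MelodySpec(
                experiment_dialect="exp1", condition=cond, inversion=bool(v % 2)
            )
            rng_seed = (cfg.seed & 0x7FFFFFFF)
            rng = np.random.default_rng([rng_seed, 7, ci, v])
            out[(cond, v)] = (
                _exp1_notes(spec, rng)
            )
    return out


def simulate_trial(
    notes: Sequence[NoteEvent],
    tempo: TempoSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "p0",
    trial_id: str = "t0",
    condition: str = "",
    expertise: str = "",
    participant_factor: float = 1.0,
    with_performance: bool = False,
) -> Tuple[List[SpanRecord], pd.DataFrame]:
    """Simulate one trial and push it through the measurement chain."""
    layout = layout_for_notes(notes)
    fixations, truth = simulate_scanpath(
        notes, layout, tempo, cfg, rng, participant_factor=participant_factor
    )
    perf = None
    if with_performance:
        perf = jittered_performance(notes, tempo, cfg.performance_jitter_sd_s, rng)
    records = compute_span_records(
        fixations,
        layout,
        notes,
        tempo,
        participant_id=participant_id,
        trial_id=trial_id,
        condition=condition,
        expertise=expertise,
        performance_onsets=perf,
        region_tag="analysis",
    )
    return records, truth


@dataclass
class TrialSim:
    """One simulated trial: its design cell, stimulus, raw fixations, ground
    truth, and (optionally) performance onsets."""

    participant_id: str
    trial_id: str
    condition: str
    expertise: str
    melody_key: str
    tempo: TempoSpec
    notes: List[NoteEvent]
    layout: ScoreLayout
    fixations: List[Fixation]
    truth: pd.DataFrame
    performance: Optional[Dict[str, float]] = None


def iter_study_trials(cfg: SimConfig, *, with_performance: bool = False):
    """Yield every trial of a simulated study.

    Each participant performs ``trials_per_tempo`` trials at each tempo with
    conditions cycling, over a fixed stimulus set shared by all participants
    (one melody per condition x variant, inversions alternating).  Every
    trial has its own random stream seeded from ``(seed, participant,
    trial)`` so any trial is independently reproducible.  The expertise
    offset applies to the "performance" group (odd participant indices).
    """
    n_trials = cfg.trials_per_tempo * len(cfg.tempi_bpm)
    n_variants = max(1, n_trials // len(_EXP1_CONDITIONS))
    melodies = _study_melodies(cfg, n_variants)
    seed = cfg.seed & 0x7FFFFFFF
    for p in range(cfg.n_participants):
        p_rng = np.random.default_rng([seed, 11, p])
        pf = float(np.exp(p_rng.normal(0.0, cfg.participant_sd)))
        expertise = "performance" if p % 2 else "education"
        for t in range(n_trials):
            cond = _EXP1_CONDITIONS[t % len(_EXP1_CONDITIONS)]
            variant = (t // len(_EXP1_CONDITIONS)) % n_variants
            bpm = cfg.tempi_bpm[t // cfg.trials_per_tempo]
            tempo = TempoSpec(bpm=bpm, phase_ref_s=0.3, performance_start_s=12.3)
            rng = np.random.default_rng([seed, 13, p, t])
            trial_cfg = cfg
            if cfg.expertise_offset_beats and expertise == "education":
                d = dict(cfg.__dict__)
                d["expertise_offset_beats"] = 0.0
                trial_cfg = SimConfig(**d)
            notes = melodies[(cond, variant)]
            layout = layout_for_notes(notes)
            fixations, truth = simulate_scanpath(
                notes, layout, tempo, trial_cfg, rng, participant_factor=pf
            )
            perf = (
                jittered_performance(notes, tempo, cfg.performance_jitter_sd_s, rng)
                if with_performance
                else None
            )
            truth = truth.assign(
                participant_id=f"p{p:03d}",
                trial_id=f"p{p:03d}-t{t:02d}",
                condition=cond,
                tempo_bpm=bpm,
            )
            yield TrialSim(
                participant_id=f"p{p:03d}",
                trial_id=f"p{p:03d}-t{t:02d}",
                condition=cond,
                expertise=expertise,
                melody_key=f"{cond}-{variant}",
                tempo=tempo,
                notes=notes,
                layout=layout,
                fixations=fixations,
                truth=truth,
                performance=perf,
            )


def simulate_study(
    cfg: SimConfig, *, with_performance: bool = False
) -> Tuple[List[SpanRecord], pd.DataFrame]:
    """Simulate a full study and push every trial through the measurement
    chain.  Returns the span records (exclusion flags set) and the
    concatenated simulator truth table."""
    all_records: List[SpanRecord] = []
    truths = []
    for trial in iter_study_trials(cfg, with_performance=with_performance):
        records = compute_span_records(
            trial.fixations,
            trial.layout,
            trial.notes,
            trial.tempo,
            participant_id=trial.participant_id,
            trial_id=trial.trial_id,
            condition=trial.condition,
            expertise=trial.expertise,
            performance_onsets=trial.performance,
            region_tag="analysis",
        )
        all_records.extend(records)
        truths.append(trial.truth)
    return all_records, pd.concat(truths, ignore_index=True)
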