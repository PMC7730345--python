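"""Span measures for first fixations on note symbols.

The central measure is the Eye-Time Span (ETS), a backward-projective span:
for a fixation *F* it is the distance, in beats, between *F*'s horizontal
position on the score (read as a metrical time scale) and the score position
where metrical time stood at *F*'s onset,

    ETS(F) = x_to_beat(F.x) - metrical_time(F.onset).

It is measured for the first fixation falling on each note's AOI, using the
fixation's actual landing position, not the AOI center.  The incoming
saccade to that fixation is the signed horizontal displacement from the
immediately preceding fixation in the raw stream, converted to beats via the
same score mapping (so non-uniform symbol spacing is handled segment by
segment rather than through a global pixels-per-beat ratio).

Records failing any of three screening rules are flagged, in order:
(i) negative ETS, (ii) regressive (leftward) incoming saccade, (iii) incoming
saccade longer than the ETS plus two beats — the last discards long
return sweeps after glances back to already-played material.  Flagged
records are left out, never replaced by the next fixation on the AOI.

Two baseline span measures are provided for comparison when a performance
log is available: the single-item lag (seconds from fixating a note to
playing it) and the forward-projective span (how far, in beats, the eyes are
ahead of the executed note at execution time).  With a mechanical
performance exactly on the metronome grid and noise-free landings, the ETS
of a note's first fixation times the beat period equals its single-item lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .score_model import Fixation, NoteEvent, ScoreLayout, assign_aoi, x_to_beat
from .sync import TempoSpec, metrical_time

__all__ = [
    "SpanRecord",
    "EXCLUSION_NONE",
    "EXCLUSION_NEG_ETS",
    "EXCLUSION_REGRESSIVE",
    "EXCLUSION_LONG_SACCADE",
    "first_fixations",
    "compute_ets",
    "incoming_saccade_beats",
    "apply_exclusions",
    "single_item_lag",
    "forward_projective_span",
    "compute_span_records",
    "exclusion_summary",
]

EXCLUSION_NONE = "none"
EXCLUSION_NEG_ETS = "neg_ets"
EXCLUSION_REGRESSIVE = "regressive"
EXCLUSION_LONG_SACCADE = "sacc_gt_ets_plus2"

#: Rule (iii) allowance: a saccade may exceed the ETS by at most this many beats.
LONG_SACCADE_ALLOWANCE_BEATS = 2.0


@dataclass
class SpanRecord:
    """Per-note first-fixation measurement with design labels and flags."""

    participant_id: str
    trial_id: str
    note_id: str
    condition: str
    note_factor: int
    tempo_bpm: float
    ets_beats: float
    saccade_beats: float  # NaN when the first fixation has no predecessor
    fix_onset_beats: float
    fix_beat_pos: float
    expertise: str = ""
    excluded: str = EXCLUSION_NONE
    ehs_lag_s: Optional[float] = None
    fps_beats: Optional[float] = None


def first_fixations(
    fixations: Sequence[Fixation],
    layout: ScoreLayout,
    notes: Sequence[NoteEvent],
) -> Dict[str, Tuple[Fixation, Optional[Fixation]]]:
    """Earliest fixation on each note's AOI, paired with its raw predecessor.

    The predecessor is the fixation immediately before in the full stream
    (whatever it landed on) — the saccade launch site.  Notes never fixated
    are absent from the map (skipping).  Fixations must be time-ordered.
    """
    for a, b in zip(fixations, fixations[1:]):
        if b.onset_s <= a.onset_s:
            raise ValueError("fixations must be strictly time-ordered")
    out: Dict[str, Tuple[Fixation, Optional[Fixation]]] = {}
    prev: Optional[Fixation] = None
    for fx in fixations:
        note_id = assign_aoi(layout, notes, fx)
        if note_id is not None and note_id not in out:
            out[note_id] = (fx, prev)
        prev = fx
    return out


def compute_ets(fx: Fixation, layout: ScoreLayout, tempo: TempoSpec) -> float:
    """ETS in beats for one fixation (may be negative; filtered later)."""
    return float(x_to_beat(layout, fx.x_px)) - float(metrical_time(fx.onset_s, tempo))


def incoming_saccade_beats(
    fx: Fixation, prev: Optional[Fixation], layout: ScoreLayout
) -> float:
    """Signed incoming saccade length in beats (negative = regressive).

    Pixel displacement is converted through the beat<->pixel map, so the
    conversion is local to the layout segments crossed.  With no predecessor
    (first fixation of a trial) the saccade is undefined and NaN is
    returned; such records drop out of the paired saccade analysis.
    """
    if prev is None:
        return math.nan
    if not prev.onset_s < fx.onset_s:
        raise ValueError("predecessor fixation must precede the first fixation")
    return float(x_to_beat(layout, fx.x_px)) - float(x_to_beat(layout, prev.x_px))


def _exclusion_flag(ets: float, saccade: float) -> str:
    # order matters: first matching rule wins
    if ets < 0:
        return EXCLUSION_NEG_ETS
    if not math.isnan(saccade):
        if saccade < 0:  # zero displacement is non-regressive
            return EXCLUSION_REGRESSIVE
        if saccade > ets + LONG_SACCADE_ALLOWANCE_BEATS:
            return EXCLUSION_LONG_SACCADE
    return EXCLUSION_NONE


def apply_exclusions(records: Iterable[SpanRecord]) -> List[SpanRecord]:
    """Set the exclusion flag on every record (idempotent, order-stable).

    Rules, first match wins: (i) ETS < 0; (ii) regressive incoming saccade
    (strictly leftward; zero displacement passes); (iii) incoming saccade
    longer than ETS + 2 beats.  Records with an undefined saccade are only
    subject to rule (i).
    """
    return [
        replace(r, excluded=_exclusion_flag(r.ets_beats, r.saccade_beats))
        for r in records
    ]


def exclusion_summary(records: Sequence[SpanRecord]) -> Dict[str, object]:
    """Counts and percentages per exclusion rule, percentages to 2 decimals."""
    total = len(records)
    counts = {
        EXCLUSION_NEG_ETS: 0,
        EXCLUSION_REGRESSIVE: 0,
        EXCLUSION_LONG_SACCADE: 0,
        EXCLUSION_NONE: 0,
    }
    for r in records:
        counts[r.excluded] += 1
    return {
        "total": total,
        "retained": counts[EXCLUSION_NONE],
        "excluded": {
            rule: {
                "count": counts[rule],
                "percent": round(100.0 * counts[rule] / total, 2) if total else 0.0,
            }
            for rule in (EXCLUSION_NEG_ETS, EXCLUSION_REGRESSIVE, EXCLUSION_LONG_SACCADE)
        },
    }


def single_item_lag(first_fix_onset_s: float, note_perf_onset_s: float) -> float:
    """Single-item-lag span: seconds from fixating a note to performing it
    (negative if the note was fixated only after being played)."""
    return note_perf_onset_s - first_fix_onset_s


def forward_projective_span(
    fixations: Sequence[Fixation],
    layout: ScoreLayout,
    tempo: TempoSpec,
    t_s: float,
) -> Tuple[float, bool]:
    """Forward-projective span at time ``t_s``: how far (in beats) the
    currently active fixation is ahead of the metrical cursor.

    Returns ``(beats, exact)`` where ``exact`` is False when no fixation was
    active at ``t_s`` and the nearest preceding fixation was used instead.
    Raises if ``t_s`` precedes the first fixation.
    """
    active = None
    exact = False
    for fx in fixations:
        if fx.onset_s <= t_s:
            active = fx
            exact = t_s < fx.onset_s + fx.duration_s
        else:
            break
    if active is None:
        raise ValueError(f"no fixation at or before t={t_s} s")
    return (
        float(x_to_beat(layout, active.x_px)) - float(metrical_time(t_s, tempo)),
        exact,
    )


def compute_span_records(
    fixations: Sequence[Fixation],
    layout: ScoreLayout,
    notes: Sequence[NoteEvent],
    tempo: TempoSpec,
    *,
    participant_id: str = "p0",
    trial_id: str = "t0",
    condition: str = "",
    expertise: str = "",
    performance_onsets: Optional[Mapping[str, float]] = None,
    region_tag: Optional[str] = None,
) -> List[SpanRecord]:
    """Run the full measurement chain for one trial.

    Extracts first fixations per AOI, computes ETS and incoming saccade for
    each, applies the exclusion rules, and — when a performance log is
    supplied — attaches the single-item lag and forward-projective baseline
    spans.  If ``region_tag`` is given, only notes carrying that tag are
    measured (analysis-region restriction); ``note_factor`` numbers the
    measured notes 1..k in score order.
    """
    if region_tag is not None:
        region = [n for n in notes if n.has_tag(region_tag)]
    else:
        region = list(notes)
    ff = first_fixations(fixations, layout, notes)
    records: List[SpanRecord] = []
    for k, note in enumerate(region, start=1):
        hit = ff.get(note.note_id)
        if hit is None:
            continue  # skipped note
        fx, prev = hit
        ets = compute_ets(fx, layout, tempo)
        sacc = incoming_saccade_beats(fx, prev, layout)
        rec = SpanRecord(
            participant_id=participant_id,
            trial_id=trial_id,
            note_id=note.note_id,
            condition=condition,
            note_factor=k,
            tempo_bpm=tempo.bpm,
            ets_beats=ets,
            saccade_beats=sacc,
            fix_onset_beats=float(metrical_time(fx.onset_s, tempo)),
            fix_beat_pos=float(x_to_beat(layout, fx.x_px)),
            expertise=expertise,
        )
        if performance_onsets is not None and note.note_id in performance_onsets:
            perf_t = performance_onsets[note.note_id]
            rec.ehs_lag_s = single_item_lag(fx.onset_s, perf_t)
            try:
                fps, _ = forward_projective_span(fixations, layout, tempo, perf_t)
                rec.fps_beats = fps
            except ValueError:
                rec.fps_beats = None
        records.append(rec)
    return apply_exclusions(records)
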