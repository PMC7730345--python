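"""Score geometry: the stimulus staff as a metrical time scale.

A simple quarter-note score can be read as a graph of metrical time: the
metronome beats are imagined to sit at the horizontal positions of the note
symbols, and any screen position between two symbols corresponds to a
fractional beat.  This module holds the note table and layout geometry and
performs the three primitive mappings the span measures are built on:

* ``x_to_beat`` — horizontal pixel position -> continuous beat position,
* ``beat_to_x`` — its exact inverse (used by the scanpath simulator),
* ``assign_aoi`` — fixation -> note symbol, via rectangular areas of
  interest (AOIs) whose horizontal cuts lie between adjacent symbols and
  whose vertical extent is the staff band plus a margin.

Coordinates follow the screen convention (x rightward, y downward).  All
span arithmetic uses x only; the vertical axis is used solely to reject
fixations that are not on the staff.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "NoteEvent",
    "Fixation",
    "ScoreLayout",
    "x_to_beat",
    "beat_to_x",
    "assign_aoi",
    "aoi_boundaries_from_notes",
    "LayoutError",
]

#: Default vertical AOI margin in pixels beyond the outermost staff lines.
DEFAULT_AOI_MARGIN_PX = 35.0


class LayoutError(ValueError):
    """Raised for inconsistent layout configuration."""


@dataclass(frozen=True)
class NoteEvent:
    """One notated symbol: its metrical onset and its pixel anchor.

    ``beat_onset`` is continuous, in quarter-note beats, 0-based at the
    start of the performance.  ``bar_index`` and ``pos_in_bar`` are 1-based
    labels only and carry no arithmetic meaning.  ``x_anchor`` is the
    horizontal reference point of the symbol — the stem in the first stimulus
    dialect, the note-head center in the second.
    """

    note_id: str
    beat_onset: float
    bar_index: int
    pos_in_bar: int
    x_anchor: float
    tags: frozenset = field(default_factory=frozenset)

    def has_tag(self, tag: str) -> bool:
        return tag in self.tags


@dataclass(frozen=True)
class Fixation:
    """One eye-tracker fixation event (detection is upstream and consumed
    as given)."""

    onset_s: float
    duration_s: float
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"fixation duration must be positive, got {self.duration_s}")


@dataclass
class ScoreLayout:
    """Monotone beat<->pixel anchor map plus the AOI geometry of one staff line.

    Parameters
    ----------
    anchors:
        Ordered ``(beat_position, x_px)`` pairs, strictly increasing in both
        coordinates.  Between anchors the beat<->pixel map is piecewise
        linear; beyond the first/last anchor it extrapolates with the
        adjacent segment's slope.
    staff_y_top, staff_y_bottom:
        Pixel rows of the outermost staff lines (y grows downward).
    aoi_vertical_margin:
        Vertical tolerance beyond the staff lines within which fixations are
        still treated as reading the notation.
    aoi_boundaries:
        Ordered pixel cut points delimiting the note AOIs: ``n + 1`` cuts
        for ``n`` notes, AOI *i* being the half-open interval
        ``[cut[i], cut[i+1])``.
    dialect:
        ``"stem_midpoint"`` — cuts midway between note stems — or
        ``"head_midpoint"`` — cuts midway between note-head centers.
    """

    anchors: Sequence[tuple]
    staff_y_top: float
    staff_y_bottom: float
    aoi_vertical_margin: float = DEFAULT_AOI_MARGIN_PX
    aoi_boundaries: Optional[Sequence[float]] = None
    dialect: str = "stem_midpoint"

    def __post_init__(self) -> None:
        anchors = [(float(b), float(x)) for b, x in self.anchors]
        if len(anchors) < 2:
            raise LayoutError("a layout needs at least two (beat, x) anchors")
        beats = [b for b, _ in anchors]
        xs = [x for _, x in anchors]
        if any(b2 <= b1 for b1, b2 in zip(beats, beats[1:])):
            raise LayoutError("anchor beat positions must be strictly increasing")
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise LayoutError("anchor x positions must be strictly increasing")
        if self.staff_y_bottom < self.staff_y_top:
            raise LayoutError("staff_y_bottom must be >= staff_y_top (y grows downward)")
        if self.dialect not in ("stem_midpoint", "head_midpoint"):
            raise LayoutError(f"unknown layout dialect {self.dialect!r}")
        if self.aoi_boundaries is not None:
            cuts = [float(c) for c in self.aoi_boundaries]
            if any(c2 <= c1 for c1, c2 in zip(cuts, cuts[1:])):
                raise LayoutError("aoi_boundaries must be strictly increasing")
            self.aoi_boundaries = cuts
        self.anchors = anchors
        self._beats = np.asarray(beats, dtype=float)
        self._xs = np.asarray(xs, dtype=float)

    # -- vertical band ----------------------------------------------------
    def y_in_band(self, y_px: float) -> bool:
        """Whether a vertical position counts as on-staff (margin included)."""
        return (
            self.staff_y_top - self.aoi_vertical_margin
            <= y_px
            <= self.staff_y_bottom + self.aoi_vertical_margin
        )


def _interp(x, xp: np.ndarray, fp: np.ndarray):
    """Piecewise-linear interpolation with linear extrapolation at the ends."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    # segment index for each query; clip so that end queries reuse edge slopes
    idx = np.clip(np.searchsorted(xp, x, side="right") - 1, 0, len(xp) - 2)
    slope = (fp[idx + 1] - fp[idx]) / (xp[idx + 1] - xp[idx])
    out = fp[idx] + slope * (x - xp[idx])
    return float(out[0]) if scalar else out


def x_to_beat(layout: ScoreLayout, x_px):
    """Map horizontal pixel position(s) to continuous beat position.

    Piecewise-linear through the layout anchors; beyond the outermost
    anchors the adjacent segment's slope is extended.  Strictly increasing
    in ``x_px``.
    """
    return _interp(x_px, layout._xs, layout._beats)


def beat_to_x(layout: ScoreLayout, beat):
    """Inverse of :func:`x_to_beat`: beat position(s) -> pixel x."""
    return _interp(beat, layout._beats, layout._xs)


def aoi_boundaries_from_notes(notes: Sequence[NoteEvent]) -> list:
    """Horizontal AOI cut points for a note row: midpoints between adjacent
    anchors, with the outer edges extended by half the adjacent gap.

    With the stem dialect this realizes cuts drawn exactly between the note
    stems; with the head dialect, midpoints between note-head centers.  For
    non-uniform spacing (e.g. wider gaps across bar lines) the first and
    last AOI of a bar come out narrower/broader, as they do on a real staff.
    """
    xs = [n.x_anchor for n in notes]
    if len(xs) < 2:
        raise LayoutError("need at least two notes to derive AOI boundaries")
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise LayoutError("note x_anchor must be strictly increasing within a staff line")
    mids = [(a + b) / 2.0 for a, b in zip(xs, xs[1:])]
    left = xs[0] - (xs[1] - xs[0]) / 2.0
    right = xs[-1] + (xs[-1] - xs[-2]) / 2.0
    return [left] + mids + [right]


def assign_aoi(
    layout: ScoreLayout, notes: Sequence[NoteEvent], fx: Fixation
) -> Optional[str]:
    """Assign a fixation to a note AOI, or ``None``.

    The fixation must lie vertically within the staff band extended by the
    AOI margin, and horizontally within the half-open interval
    ``[cut[i], cut[i+1])`` of note *i*.  A fixation exactly on a cut point
    belongs to the right-hand AOI (deterministic, partition-preserving).
    """
    cuts = layout.aoi_boundaries
    if cuts is None:
        cuts = aoi_boundaries_from_notes(notes)
    if len(cuts) != len(notes) + 1:
        raise LayoutError(
            f"{len(notes)} notes need {len(notes) + 1} AOI boundaries, got {len(cuts)}"
        )
    if not layout.y_in_band(fx.y_px):
        return None
    i = bisect.bisect_right(cuts, fx.x_px) - 1
    if i < 0 or i >= len(notes):
        return None
    return notes[i].note_id


def validate_notes(notes: Iterable[NoteEvent]) -> None:
    """Check the note-table invariants (monotone beats and anchors)."""
    notes = list(notes)
    for a, b in zip(notes, notes[1:]):
        if b.beat_onset <= a.beat_onset:
            raise LayoutError(
                f"beat_onset must be strictly increasing ({a.note_id} -> {b.note_id})"
            )
        if b.x_anchor <= a.x_anchor:
            raise LayoutError(
                f"x_anchor must be strictly increasing ({a.note_id} -> {b.note_id})"
            )
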