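"""Metronome synchronization: anchoring metrical time to recording time.

The performance tempo is regulated by a metronome, so musical time advances
in beats of 60/bpm seconds.  The eye tracker records in clock time; to index
fixation onsets in beats we need (a) the beat period and (b) where the
metronome clicks sit within the recording clock.  The click phase is
estimated from synchronization timestamps (key presses produced on clicks):
each timestamp's residue modulo the beat period estimates the click offset,
and their circular median is the phase reference.  The performance start is
then snapped to the nearest click and fixation onsets are expressed as
``(t - start) / period`` beats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TempoSpec", "estimate_click_phase", "metrical_time", "snap_to_click"]

logger = logging.getLogger(__name__)


@dataclass
class TempoSpec:
    """One tempo segment: bpm plus the click phase anchoring beats to clock time.

    Attributes
    ----------
    bpm:
        Metronome tempo in beats per minute (> 0).
    phase_ref_s:
        Estimated click offset within one beat period, in seconds,
        in ``[0, beat_period_s)``.
    segment_start_s:
        Recording time at which this tempo takes effect (for sessions with a
        pre-programmed tempo change each segment carries its own spec).
    performance_start_s:
        Recording time of performance beat 0, snapped to the click grid on
        use.
    """

    bpm: float
    phase_ref_s: float = 0.0
    segment_start_s: float = 0.0
    performance_start_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.bpm > 0:
            raise ValueError(f"bpm must be positive, got {self.bpm}")
        if not np.isfinite(self.phase_ref_s):
            raise ValueError(f"phase_ref_s must be finite, got {self.phase_ref_s}")
        # normalize into [0, period); a phase is only defined modulo the period
        self.phase_ref_s = self.phase_ref_s % self.beat_period_s
        if self.phase_ref_s == self.beat_period_s:  # float wrap at the boundary
            self.phase_ref_s = 0.0

    @property
    def beat_period_s(self) -> float:
        """Duration of one beat in seconds (60/bpm)."""
        return 60.0 / self.bpm


def _circular_distance(a: np.ndarray, b: float, period: float) -> np.ndarray:
    d = np.abs(a - b) % period
    return np.minimum(d, period - d)


def estimate_click_phase(timestamps: Sequence[float], beat_period_s: float) -> float:
    """Estimate the metronome click offset within one beat period.

    Takes the residues of the timestamps modulo the beat period and returns
    their circular median: the residue that minimizes the summed circular
    distance to all residues on the period circle.  Away from the wrap
    boundary this coincides with the ordinary median of the residues; at the
    boundary (clicks near a whole period) the ordinary median is misleading
    while the circular median is not.

    A dispersion larger than a quarter period is logged as a warning (poor
    synchronization), not raised.
    """
    ts = np.asarray(list(timestamps), dtype=float)
    if ts.size == 0:
        raise ValueError("no synchronization timestamps supplied")
    if not beat_period_s > 0:
        raise ValueError("beat_period_s must be positive")
    residues = np.sort(ts % beat_period_s)
    # brute-force circular median over the observed residues; ties -> smallest
    costs = [
        _circular_distance(residues, float(r), beat_period_s).sum() for r in residues
    ]
    phase = float(residues[int(np.argmin(costs))])
    dispersion = float(
        np.median(_circular_distance(residues, phase, beat_period_s)) * 2.0
    )
    if dispersion > beat_period_s / 4.0:
        logger.warning(
            "click-phase dispersion %.4f s exceeds a quarter period (%.4f s): "
            "poor synchronization",
            dispersion,
            beat_period_s / 4.0,
        )
    return phase % beat_period_s


def snap_to_click(t_s: float, tempo: TempoSpec) -> float:
    """Snap a recording time to the nearest metronome click implied by the
    tempo's phase reference."""
    period = tempo.beat_period_s
    k = round((t_s - tempo.phase_ref_s) / period)
    return tempo.phase_ref_s + k * period


def metrical_time(t_s: float, tempo: TempoSpec) -> float:
    """Metrical time of appearance, in beats, of a recording-time instant.

    The performance start is first snapped to the click grid; the result is
    ``(t_s - snapped_start) / beat_period_s``.  Negative values (instants
    before the performance start) are legal output and flagged downstream.
    """
    start = snap_to_click(tempo.performance_start_s, tempo)
    out = (np.asarray(t_s, dtype=float) - start) / tempo.beat_period_s
    return float(out) if out.ndim == 0 else out
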