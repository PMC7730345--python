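"""File formats and run configuration.

Input formats are deliberately plain: fixation events come as delimited text
(one row per fixation with onset and duration in milliseconds — the
eye-tracker export convention — and screen coordinates in pixels), the
layout/tempo configuration as JSON or YAML validated against a schema, and
optional performance logs as CSV of note id and onset in milliseconds.
Outputs are CSV span tables with a JSON sidecar carrying the exclusion
summary, the configuration hash, and the seed, so a run is reproducible and
auditable from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .score_model import Fixation, NoteEvent, ScoreLayout
from .spans import SpanRecord, exclusion_summary
from .stats import records_to_frame
from .sync import TempoSpec, estimate_click_phase

__all__ = [
    "NoteConfig",
    "LayoutConfig",
    "TempoSegmentConfig",
    "RunConfig",
    "load_config",
    "read_fixations",
    "read_performance_log",
    "write_spans",
    "read_spans",
    "config_hash",
]

FIXATION_COLUMNS = ["participant", "trial", "onset_ms", "duration_ms", "x_px", "y_px"]


class NoteConfig(BaseModel):
    id: str
    beat: float
    bar: int = 1
    pos: int = 1
    x: float
    tags: List[str] = Field(default_factory=list)

    def to_note(self) -> NoteEvent:
        return NoteEvent(
            note_id=self.id,
            beat_onset=self.beat,
            bar_index=self.bar,
            pos_in_bar=self.pos,
            x_anchor=self.x,
            tags=frozenset(self.tags),
        )


class LayoutConfig(BaseModel):
    anchors: List[Tuple[float, float]]
    staff_y_top: float
    staff_y_bottom: float
    aoi_vertical_margin: float = 35.0
    aoi_boundaries: Optional[List[float]] = None
    dialect: str = "stem_midpoint"

    def to_layout(self) -> ScoreLayout:
        return ScoreLayout(
            anchors=[tuple(a) for a in self.anchors],
            staff_y_top=self.staff_y_top,
            staff_y_bottom=self.staff_y_bottom,
            aoi_vertical_margin=self.aoi_vertical_margin,
            aoi_boundaries=self.aoi_boundaries,
            dialect=self.dialect,
        )


class TempoSegmentConfig(BaseModel):
    bpm: float
    segment_start_s: float = 0.0
    performance_start_s: float = 0.0
    phase_ref_s: Optional[float] = None
    sync_timestamps_s: List[float] = Field(default_factory=list)

    @field_validator("bpm")
    @classmethod
    def _bpm_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("bpm must be positive")
        return v

    def to_tempo(self) -> TempoSpec:
        """Build the tempo spec, estimating the click phase from the
        synchronization timestamps when it is not given explicitly."""
        period = 60.0 / self.bpm
        if self.phase_ref_s is not None:
            phase = self.phase_ref_s % period
        elif self.sync_timestamps_s:
            phase = estimate_click_phase(self.sync_timestamps_s, period)
        else:
            phase = 0.0
        return TempoSpec(
            bpm=self.bpm,
            phase_ref_s=phase,
            segment_start_s=self.segment_start_s,
            performance_start_s=self.performance_start_s,
        )


class RunConfig(BaseModel):
    """Trial configuration: geometry, notes, tempo segments, analysis region."""

    layout: LayoutConfig
    notes: List[NoteConfig]
    tempo_segments: List[TempoSegmentConfig]
    analysis_tag: Optional[str] = None
    seed: int = 0

    def to_objects(self) -> Tuple[ScoreLayout, List[NoteEvent], List[TempoSpec]]:
        return (
            self.layout.to_layout(),
            [n.to_note() for n in self.notes],
            [t.to_tempo() for t in self.tempo_segments],
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return RunConfig.model_validate(data)


def config_hash(obj) -> str:
    """Stable short hash of a configuration (pydantic model or plain data)."""
    if isinstance(obj, BaseModel):
        obj = obj.model_dump()
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_fixations(
    path: Union[str, Path], sep: str = "\t"
) -> Dict[Tuple[str, str], List[Fixation]]:
    """Read a fixation table into per-(participant, trial) fixation lists.

    Expects columns ``participant, trial, onset_ms, duration_ms, x_px,
    y_px``; times are milliseconds and converted to seconds.  Onsets must be
    strictly increasing within a trial; violations are reported with their
    row number.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df[FIXATION_COLUMNS[2:]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed rows (1-based, after header): "
                         f"{[int(i) + 2 for i in bad[:10]]}")
    out: Dict[Tuple[str, str], List[Fixation]] = {}
    for (p, t), g in df.groupby(["participant", "trial"], sort=True):
        onsets = g["onset_ms"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            row = int(g.index[np.argmax(np.diff(onsets) <= 0) + 1]) + 2
            raise ValueError(
                f"{path}: fixation onsets not strictly increasing within trial "
                f"({p}, {t}) at row {row}"
            )
        out[(str(p), str(t))] = [
            Fixation(
                onset_s=r.onset_ms / 1000.0,
                duration_s=r.duration_ms / 1000.0,
                x_px=float(r.x_px),
                y_px=float(r.y_px),
            )
            for r in g.itertuples()
        ]
    return out


def read_performance_log(path: Union[str, Path]) -> Dict[str, float]:
    """Performance log CSV (columns ``note_id, onset_ms``) -> onsets in s."""
    df = pd.read_csv(path)
    for c in ("note_id", "onset_ms"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return {str(r.note_id): r.onset_ms / 1000.0 for r in df.itertuples()}


def write_spans(
    records: Union[Sequence[SpanRecord], pd.DataFrame],
    path: Union[str, Path],
    metadata: Optional[dict] = None,
) -> Path:
    """Write span records as CSV plus an exclusion-summary JSON sidecar.

    The CSV has a stable column order; the sidecar (``<stem>.summary.json``)
    carries per-rule exclusion counts and percentages (2 decimals) plus any
    metadata (seed, config hash).  Output is byte-identical across runs on
    identical input.
    """
    path = Path(path)
    df = records_to_frame(records)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)  # default float repr round-trips exactly
    if isinstance(records, pd.DataFrame):
        summary = _summary_from_frame(df)
    else:
        summary = exclusion_summary(list(records))
    sidecar = path.with_suffix(".summary.json")
    payload = {"exclusions": summary, "metadata": metadata or {}}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


def _summary_from_frame(df: pd.DataFrame) -> dict:
    from .spans import (
        EXCLUSION_LONG_SACCADE,
        EXCLUSION_NEG_ETS,
        EXCLUSION_NONE,
        EXCLUSION_REGRESSIVE,
    )

    total = len(df)
    counts = df["excluded"].value_counts().to_dict() if total else {}
    return {
        "total": total,
        "retained": int(counts.get(EXCLUSION_NONE, 0)),
        "excluded": {
            rule: {
                "count": int(counts.get(rule, 0)),
                "percent": round(100.0 * counts.get(rule, 0) / total, 2) if total else 0.0,
            }
            for rule in (EXCLUSION_NEG_ETS, EXCLUSION_REGRESSIVE, EXCLUSION_LONG_SACCADE)
        },
    }


def read_spans(path: Union[str, Path]) -> pd.DataFrame:
    """Round-trip reader for the span CSV."""
    return pd.read_csv(path)
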