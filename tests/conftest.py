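import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from etspan.score_model import Fixation, NoteEvent, ScoreLayout
from etspan.sync import TempoSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def uniform_layout():
    """Nine quarter notes, 15 px apart, one beat per note (stem dialect)."""
    anchors = [(float(i), 100.0 + 15.0 * i) for i in range(9)]
    return ScoreLayout(
        anchors=anchors,
        staff_y_top=500.0,
        staff_y_bottom=534.0,
        aoi_vertical_margin=35.0,
        aoi_boundaries=[100.0 + 15.0 * i - 7.5 for i in range(10)],
    )


@pytest.fixture
def uniform_notes():
    return [
        NoteEvent(
            note_id=f"n{i}",
            beat_onset=float(i),
            bar_index=i // 4 + 1,
            pos_in_bar=i % 4 + 1,
            x_anchor=100.0 + 15.0 * i,
        )
        for i in range(9)
    ]


@pytest.fixture
def tempo_60():
    """60 bpm, clicks on whole seconds, performance starting at 12.0 s."""
    return TempoSpec(bpm=60.0, phase_ref_s=0.0, performance_start_s=12.0)


def sweep_fixations(layout, notes, start_s=12.0, step_s=1.0):
    """Left-to-right one-fixation-per-note scanpath along the anchors."""
    return [
        Fixation(
            onset_s=start_s + i * step_s,
            duration_s=step_s * 0.9,
            x_px=n.x_anchor,
            y_px=(layout.staff_y_top + layout.staff_y_bottom) / 2,
        )
        for i, n in enumerate(notes)
    ]
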