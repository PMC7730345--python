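import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from etspan.score_model import Fixation
from etspan.spans import (
    EXCLUSION_LONG_SACCADE,
    EXCLUSION_NEG_ETS,
    EXCLUSION_NONE,
    EXCLUSION_REGRESSIVE,
    SpanRecord,
    apply_exclusions,
    compute_ets,
    compute_span_records,
    exclusion_summary,
    first_fixations,
    forward_projective_span,
    incoming_saccade_beats,
    single_item_lag,
)
from etspan.sync import TempoSpec, metrical_time

from conftest import sweep_fixations


def mid(layout):
    return (layout.staff_y_top + layout.staff_y_bottom) / 2


class TestFirstFixations:
    def test_sweep_maps_each_note_to_own_fixation(self, uniform_layout, uniform_notes):
        fxs = sweep_fixations(uniform_layout, uniform_notes)
        ff = first_fixations(fxs, uniform_layout, uniform_notes)
        assert set(ff) == {n.note_id for n in uniform_notes}
        for i, n in enumerate(uniform_notes):
            fx, prev = ff[n.note_id]
            assert fx is fxs[i]
            assert prev is (fxs[i - 1] if i else None)

    def test_refixation_keeps_earlier(self, uniform_layout, uniform_notes):
        y = mid(uniform_layout)
        fxs = [
            Fixation(10.0, 0.3, 101.0, y),
            Fixation(10.5, 0.3, 116.0, y),
            Fixation(11.0, 0.3, 99.0, y),  # back to the first note
        ]
        ff = first_fixations(fxs, uniform_layout, uniform_notes)
        assert ff["n0"][0] is fxs[0]

    def test_skipped_note_absent(self, uniform_layout, uniform_notes):
        fxs = sweep_fixations(uniform_layout, uniform_notes)
        del fxs[3]
        ff = first_fixations(fxs, uniform_layout, uniform_notes)
        assert "n3" not in ff
        # the note after the skip keeps its raw-stream predecessor
        assert ff["n4"][1].x_px == uniform_notes[2].x_anchor

    def test_out_of_order_fixations_rejected(self, uniform_layout, uniform_notes):
        y = mid(uniform_layout)
        fxs = [Fixation(10.0, 0.3, 101.0, y), Fixation(9.0, 0.3, 116.0, y)]
        with pytest.raises(ValueError):
            first_fixations(fxs, uniform_layout, uniform_notes)


class TestComputeEts:
    def test_schematic_1p5_beats(self, uniform_layout, tempo_60):
        # fixation midway between the notes of beats 3 and 4, two beats
        # after the performance start: landing 3.5 - cursor 2.0 = 1.5
        fx = Fixation(onset_s=14.0, duration_s=0.3, x_px=100.0 + 15 * 3.5, y_px=517.0)
        assert compute_ets(fx, uniform_layout, tempo_60) == pytest.approx(1.5, abs=1e-9)

    def test_schematic_2p5_beats(self, uniform_layout, tempo_60):
        fx = Fixation(onset_s=14.0, duration_s=0.3, x_px=100.0 + 15 * 4.5, y_px=517.0)
        assert compute_ets(fx, uniform_layout, tempo_60) == pytest.approx(2.5, abs=1e-9)

    def test_zero_at_metrical_cursor(self, uniform_layout, tempo_60):
        fx = Fixation(onset_s=14.0, duration_s=0.3, x_px=100.0 + 15 * 2.0, y_px=517.0)
        assert compute_ets(fx, uniform_layout, tempo_60) == pytest.approx(0.0, abs=1e-12)

    def test_uses_actual_landing_not_aoi_center(self, uniform_layout, tempo_60):
        a = Fixation(onset_s=14.0, duration_s=0.3, x_px=100.0 + 15 * 3.0, y_px=517.0)
        b = Fixation(onset_s=14.0, duration_s=0.3, x_px=100.0 + 15 * 3.2, y_px=517.0)
        d = compute_ets(b, uniform_layout, tempo_60) - compute_ets(a, uniform_layout, tempo_60)
        assert d == pytest.approx(0.2, abs=1e-9)

    @given(st.floats(-20, 20))
    def test_invariant_under_rigid_time_shift(self, delta):
        from etspan.score_model import ScoreLayout

        layout = ScoreLayout(
            anchors=[(float(i), 100.0 + 15 * i) for i in range(9)],
            staff_y_top=500.0,
            staff_y_bottom=534.0,
        )
        t0 = TempoSpec(bpm=60.0, phase_ref_s=0.0, performance_start_s=12.0)
        period = t0.beat_period_s
        t1 = TempoSpec(
            bpm=60.0, phase_ref_s=(0.0 + delta) % period, performance_start_s=12.0 + delta
        )
        fx0 = Fixation(onset_s=14.2, duration_s=0.3, x_px=160.0, y_px=517.0)
        fx1 = Fixation(onset_s=14.2 + delta, duration_s=0.3, x_px=160.0, y_px=517.0)
        assert compute_ets(fx0, layout, t0) == pytest.approx(
            compute_ets(fx1, layout, t1), abs=1e-7
        )


class TestIncomingSaccade:
    def test_one_note_spacing_is_one_beat(self, uniform_layout):
        prev = Fixation(10.0, 0.3, 130.0, 517.0)
        fx = Fixation(10.5, 0.3, 145.0, 517.0)
        assert incoming_saccade_beats(fx, prev, uniform_layout) == pytest.approx(1.0, abs=1e-12)

    def test_regressive_is_negative(self, uniform_layout):
        prev = Fixation(10.0, 0.3, 160.0, 517.0)
        fx = Fixation(10.5, 0.3, 130.0, 517.0)
        assert incoming_saccade_beats(fx, prev, uniform_layout) < 0

    def test_conversion_is_segment_local(self):
        from etspan.score_model import ScoreLayout

        # 15 px/beat before the bar line, 30 px/beat after it
        layout = ScoreLayout(
            anchors=[(0, 100), (1, 115), (2, 145)],
            staff_y_top=500.0,
            staff_y_bottom=534.0,
        )
        prev = Fixation(10.0, 0.3, 100.0, 517.0)
        fx = Fixation(10.5, 0.3, 115.0, 517.0)
        assert incoming_saccade_beats(fx, prev, layout) == pytest.approx(1.0, abs=1e-12)
        prev2 = Fixation(11.0, 0.3, 115.0, 517.0)
        fx2 = Fixation(11.5, 0.3, 145.0, 517.0)
        assert incoming_saccade_beats(fx2, prev2, layout) == pytest.approx(1.0, abs=1e-12)

    def test_missing_predecessor_is_nan(self, uniform_layout):
        fx = Fixation(10.5, 0.3, 130.0, 517.0)
        assert math.isnan(incoming_saccade_beats(fx, None, uniform_layout))


def make_record(ets, sacc, **kw):
    return SpanRecord(
        participant_id="p0",
        trial_id="t0",
        note_id=kw.get("note_id", "n0"),
        condition="stepwise",
        note_factor=1,
        tempo_bpm=60.0,
        ets_beats=ets,
        saccade_beats=sacc,
        fix_onset_beats=0.0,
        fix_beat_pos=ets,
    )


def brute_force_flag(ets, sacc):
    """Independent restatement of the screening rules."""
    if ets < 0:
        return EXCLUSION_NEG_ETS
    if not math.isnan(sacc) and sacc < 0:
        return EXCLUSION_REGRESSIVE
    if not math.isnan(sacc) and sacc > ets + 2.0:
        return EXCLUSION_LONG_SACCADE
    return EXCLUSION_NONE


class TestExclusions:
    def test_toy_set_single_survivor(self):
        recs = [make_record(*p) for p in [(2.0, 1.0), (-0.1, 0.5), (2.0, -0.3), (1.0, 3.5)]]
        flagged = apply_exclusions(recs)
        assert [r.excluded for r in flagged] == [
            EXCLUSION_NONE,
            EXCLUSION_NEG_ETS,
            EXCLUSION_REGRESSIVE,
            EXCLUSION_LONG_SACCADE,
        ]

    def test_all_clean_identity(self):
        recs = [make_record(2.0, 1.0), make_record(0.5, 0.0)]
        assert all(r.excluded == EXCLUSION_NONE for r in apply_exclusions(recs))

    def test_exhaustive_brute_force_equivalence(self):
        ets_grid = [-0.5, -1e-9, 0.0, 0.3, 1.0, 2.0, 3.5]
        sacc_grid = [-2.0, -1e-9, 0.0, 0.5, 1.0, 2.0 + 1e-9, 3.0, 5.5, math.nan]
        for e in ets_grid:
            for s in sacc_grid:
                got = apply_exclusions([make_record(e, s)])[0].excluded
                assert got == brute_force_flag(e, s), (e, s)

    def test_idempotent(self):
        recs = [make_record(e, s) for e in (-1, 0.5, 2) for s in (-1, 0.5, 5)]
        once = apply_exclusions(recs)
        twice = apply_exclusions(once)
        assert [r.excluded for r in once] == [r.excluded for r in twice]

    def test_zero_saccade_not_regressive(self):
        assert apply_exclusions([make_record(1.0, 0.0)])[0].excluded == EXCLUSION_NONE

    def test_survivors_satisfy_invariants(self):
        rng = np.random.default_rng(5)
        recs = [
            make_record(float(e), float(s))
            for e, s in zip(rng.normal(1, 2, 200), rng.normal(1, 2, 200))
        ]
        for r in apply_exclusions(recs):
            if r.excluded == EXCLUSION_NONE:
                assert r.ets_beats >= 0
                assert r.saccade_beats >= 0
                assert r.saccade_beats <= r.ets_beats + 2.0

    def test_summary_percentages(self):
        recs = [make_record(2.0, 1.0)] * 3 + [make_record(-1.0, 0.5)]
        s = exclusion_summary(apply_exclusions(recs))
        assert s["total"] == 4
        assert s["excluded"][EXCLUSION_NEG_ETS] == {"count": 1, "percent": 25.0}


class TestBaselineSpans:
    def test_single_item_lag(self):
        assert single_item_lag(10.0, 11.3) == pytest.approx(1.3)
        assert single_item_lag(10.0, 10.0) == 0.0
        assert single_item_lag(12.0, 11.0) == pytest.approx(-1.0)

    def test_forward_projective_active_fixation(self, uniform_layout, tempo_60):
        fxs = [
            Fixation(13.0, 1.0, 100.0 + 15 * 4.0, 517.0),
            Fixation(14.0, 1.0, 100.0 + 15 * 6.0, 517.0),
        ]
        # at t=14.0 the cursor is at beat 2 and the active fixation at beat 6
        val, exact = forward_projective_span(fxs, uniform_layout, tempo_60, 14.0)
        assert val == pytest.approx(4.0, abs=1e-9)
        assert exact

    def test_forward_projective_constant_within_fixation(self, uniform_layout, tempo_60):
        fxs = [Fixation(13.0, 2.0, 100.0 + 15 * 5.0, 517.0)]
        v1, _ = forward_projective_span(fxs, uniform_layout, tempo_60, 13.0)
        v2, _ = forward_projective_span(fxs, uniform_layout, tempo_60, 14.5)
        # the fixated position is constant; the cursor moved 1.5 beats
        assert v1 - v2 == pytest.approx(1.5, abs=1e-9)

    def test_forward_projective_differs_from_ets_between_onsets(
        self, uniform_layout, tempo_60
    ):
        # probing mid-fixation: ETS is anchored at the fixation onset, the
        # forward span at the probe time, so they differ by the elapsed beats
        fx = Fixation(13.0, 2.0, 100.0 + 15 * 5.0, 517.0)
        ets = compute_ets(fx, uniform_layout, tempo_60)
        fps_onset, _ = forward_projective_span([fx], uniform_layout, tempo_60, 13.0)
        fps_later, _ = forward_projective_span([fx], uniform_layout, tempo_60, 14.0)
        assert fps_onset == pytest.approx(ets, abs=1e-9)
        assert fps_later == pytest.approx(ets - 1.0, abs=1e-9)

    def test_before_first_fixation_errors(self, uniform_layout, tempo_60):
        fxs = [Fixation(13.0, 1.0, 130.0, 517.0)]
        with pytest.raises(ValueError):
            forward_projective_span(fxs, uniform_layout, tempo_60, 12.0)


class TestChainIdentity:
    def test_consecutive_first_fixations(self, uniform_layout, uniform_notes, tempo_60):
        rng = np.random.default_rng(7)
        y = mid(uniform_layout)
        fxs = []
        t = 12.1
        for n in uniform_notes:
            t += rng.uniform(0.3, 0.9)
            fxs.append(Fixation(t, 0.25, n.x_anchor + rng.uniform(-5, 5), y))
        recs = compute_span_records(
            fxs, uniform_layout, uniform_notes, tempo_60, condition="c"
        )
        for r1, r2 in zip(recs, recs[1:]):
            delta = r2.fix_onset_beats - r1.fix_onset_beats
            assert r2.ets_beats == pytest.approx(
                r1.ets_beats - delta + r2.saccade_beats, abs=1e-9
            )


class TestMechanicalEquivalence:
    def test_lag_equals_ets_times_period(self, uniform_layout, uniform_notes, tempo_60):
        from etspan.simulate import mechanical_performance

        fxs = sweep_fixations(uniform_layout, uniform_notes, start_s=11.0, step_s=0.8)
        perf = mechanical_performance(uniform_notes, tempo_60)
        recs = compute_span_records(
            fxs,
            uniform_layout,
            uniform_notes,
            tempo_60,
            performance_onsets=perf,
        )
        assert recs
        for r in recs:
            assert r.ehs_lag_s == pytest.approx(
                r.ets_beats * tempo_60.beat_period_s, abs=1e-9
            )
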