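import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitmode as gm
from gaitmode.event_detector import GaitEvent
from gaitmode.preprocess import ProcessedTrial
from gaitmode.transition_predictor import (
    STEP_MS_DEFAULT,
    WIN_MS_DEFAULT,
    StanceSegment,
    mode_at,
)


def _ev(kind, t):
    return GaitEvent(kind, "right", t)


class TestSegmentStance:
    def test_pairing(self):
        events = [_ev("FC", 1.0), _ev("TO", 1.6), _ev("FC", 2.1), _ev("TO", 2.7)]
        assert gm.segment_stance(events) == [(1.0, 1.6), (2.1, 2.7)]

    def test_trailing_fc_dropped(self):
        events = [_ev("FC", 1.0), _ev("TO", 1.6), _ev("FC", 2.1)]
        assert gm.segment_stance(events) == [(1.0, 1.6)]

    def test_empty(self):
        assert gm.segment_stance([]) == []


class TestLabelTransitions:
    timeline = [("W", 0.0, 2.0), ("RA1", 2.0, 4.0), ("RA2", 4.0, 6.0)]

    def test_walking_to_ramp_collapses_incline(self):
        segs = gm.label_transitions(self.timeline, [(1.0, 1.6), (2.1, 2.7)])
        assert segs[0].from_mode == "W" and segs[0].to_mode == "RA1"
        assert segs[0].transition == "W->RA"

    def test_same_mode_ramp_transition(self):
        tl = [("RA2", 0.0, 10.0)]
        segs = gm.label_transitions(tl, [(1.0, 1.6), (2.1, 2.7)])
        assert segs[0].transition == "RA2->RA2"

    def test_out_of_vocabulary_flagged(self):
        tl = [("RA1", 0.0, 2.0), ("SD", 2.0, 4.0)]
        segs = gm.label_transitions(tl, [(1.0, 1.6), (2.1, 2.7)])
        assert segs[0].transition is None

    def test_boundary_time_belongs_to_starting_segment(self):
        assert mode_at(self.timeline, 2.0) == "RA1"

    def test_time_outside_timeline_rejected(self):
        with pytest.raises(ValueError):
            gm.label_transitions(self.timeline, [(1.0, 1.6), (7.0, 7.6)])

    def test_vocabulary_families_disjoint_and_complete(self):
        fams = list(gm.FAMILIES.values())
        assert sum(len(f) for f in fams) == 19
        assert len(set(gm.TRANSITIONS)) == 19


def make_constant_processed(n_seconds=2.0, rate=2000.0, emg_value=1.0):
    n = int(n_seconds * rate)
    return ProcessedTrial(
        subject_id=0,
        trial_id=0,
        emg_env=np.full((20, n), emg_value),
        imu_norm=np.zeros((42, n)),
        rate_hz=rate,
        mode_timeline=[("W", 0.0, n_seconds)],
        true_events=[],
    )


class TestMakeWindows:
    def test_count_formula_600ms(self):
        proc = make_constant_processed()
        seg = StanceSegment(0.2, 0.8, "W", "W", "W->W")
        wins = gm.make_windows(proc, seg)
        assert len(wins) == 42  # floor((600-100)/12) + 1

    def test_single_window_boundary(self):
        proc = make_constant_processed()
        seg = StanceSegment(0.2, 0.3, "W", "W", "W->W")
        assert len(gm.make_windows(proc, seg)) == 1

    def test_short_stance_warns_and_empty(self):
        proc = make_constant_processed()
        seg = StanceSegment(0.2, 0.25, "W", "W", "W->W")
        with pytest.warns(UserWarning):
            assert gm.make_windows(proc, seg) == []

    def test_constant_emg_feature(self):
        proc = make_constant_processed(emg_value=1.0)
        seg = StanceSegment(0.2, 0.8, "W", "W", "W->W")
        for w in gm.make_windows(proc, seg):
            np.testing.assert_allclose(w.feature[:20], 1.0)
            assert w.feature.shape == (62,)
            assert w.end_s - w.start_s == pytest.approx(0.1)

    @given(
        duration_ms=st.floats(10, 2000),
        win_ms=st.floats(20, 300),
        step_ms=st.floats(1, 50),
    )
    @settings(deadline=None, max_examples=200)
    def test_count_matches_brute_force(self, duration_ms, win_ms, step_ms):
        n = gm.window_count(duration_ms, win_ms, step_ms)
        # brute force: place windows until the end passes the stance end
        k = 0
        while k * step_ms + win_ms <= duration_ms + 1e-9:
            k += 1
        assert n == k


class TestVote:
    def test_plurality(self):
        assert gm.vote(["A", "A", "B"]) == "A"

    def test_tie_broken_by_summed_probability(self):
        assert gm.vote(["A", "B"], [0.7, 0.6], class_order=["B", "A"]) == "A"
        assert gm.vote(["A", "B"], [0.6, 0.7], class_order=["B", "A"]) == "B"

    def test_tie_broken_by_class_index_last(self):
        assert gm.vote(["A", "B"], [0.5, 0.5], class_order=["B", "A"]) == "B"

    def test_single_window(self):
        assert gm.vote(["C"]) == "C"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gm.vote([])

    @given(
        labels=st.lists(st.sampled_from("ABCD"), min_size=1, max_size=30),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_exhaustive_counting(self, labels):
        counts = collections.Counter(labels)
        top = counts.most_common(1)[0][1]
        tied = sorted(lab for lab, c in counts.items() if c == top)
        # with no probabilities the tie-break falls through to class order
        assert gm.vote(labels, class_order=list("ABCD")) == tied[0]


@pytest.fixture(scope="module")
def model_and_windows():
    proc = make_constant_processed()
    rng = np.random.default_rng(0)
    # two-class training windows with offset features
    wins, labels = [], []
    for i in range(60):
        f = rng.normal(0, 0.05, 62) + (1.0 if i % 2 else -1.0)
        wins.append(gm.AnalysisWindow(0.0, 0.1, f))
        labels.append("W->W" if i % 2 else "W->ST")
    model = gm.train_transition_model(
        wins, labels, ["W->W", "W->ST"], seed=0, max_epochs=30,
        early_stop_patience=10,
    )
    seg = StanceSegment(0.2, 0.8, "W", "W", "W->W")
    stance_wins = gm.make_windows(proc, seg)
    return model, stance_wins


class TestPredictAtOffset:
    def test_offset_zero_equals_full_vote(self, model_and_windows):
        model, wins = model_and_windows
        labels, probs = model.predict_windows(wins)
        full = gm.vote(labels, probs, class_order=model.classes)
        assert gm.predict_at_offset(model, wins, 0.8, 0.0) == full

    def test_offset_beyond_stance_undecidable(self, model_and_windows):
        model, wins = model_and_windows
        assert gm.predict_at_offset(model, wins, 0.8, 2000.0) == gm.UNDECIDABLE

    def test_window_sets_nested_across_offsets(self, model_and_windows):
        _, wins = model_and_windows
        to_time = 0.8

        def eligible(off):
            return {w.start_s for w in wins if w.end_s <= to_time - off / 1000.0 + 1e-9}

        for o1, o2 in [(0, 50), (50, 150), (150, 350)]:
            assert eligible(o2) <= eligible(o1)

    def test_offset_window_count_formula(self, model_and_windows):
        _, wins = model_and_windows
        off = 50.0
        n_eligible = len([w for w in wins if w.end_s <= 0.8 - off / 1000.0 + 1e-9])
        assert n_eligible == gm.window_count(600.0 - off, WIN_MS_DEFAULT, STEP_MS_DEFAULT)
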