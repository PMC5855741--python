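"""Track linking and merge/split event classification."""

import numpy as np
import pytest

from focidyn import tracking as trk
from focidyn.segmentation import FocusDetection
from focidyn.synthetic import SimulationConfig, simulate_confined_tracks, _draw_anchors


def _det(frame, x, y, label=1, area=1.0, intensity=100.0, border=False):
    return FocusDetection(frame=frame, label=label, x=x, y=y, area=area,
                          mean_intensity=intensity, touches_border=border)


class TestLinking:
    def test_single_static_focus_single_track(self):
        dets = [_det(t, 1.0, 1.0) for t in range(20)]
        tracks = trk.link_tracks(dets, linking_radius=0.5)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 20

    def test_distant_foci_never_swap(self):
        dets = []
        for t in range(15):
            dets.append(_det(t, 0.0, 0.0, label=1))
            dets.append(_det(t, 10.0, 10.0, label=2))
        tracks = trk.link_tracks(dets, linking_radius=1.0)
        assert len(tracks) == 2
        for tr in tracks:
            labels = {d.label for d in tr.detections}
            assert len(labels) == 1

    def test_gap_bridging(self):
        dets = [_det(t, 1.0, 1.0) for t in range(10) if t != 4]
        tracks = trk.link_tracks(dets, linking_radius=0.5, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].gaps == 1

    def test_invalid_radius_errors(self):
        with pytest.raises(ValueError):
            trk.link_tracks([], linking_radius=0.0)

    def test_ou_tracks_linked_correctly(self):
        # confined foci at the reported frame rate; radius 3*sqrt(4*Dc*dt)
        cfg = SimulationConfig(condition="control", Dc_true=0.01, rc_true=0.5, seed=2)
        rng = np.random.default_rng(2)
        anchors = _draw_anchors(8, cfg, rng)
        tracks_xy = simulate_confined_tracks(8, cfg, rng, anchors=anchors)
        dets = [
            _det(t, tracks_xy[i, t, 0], tracks_xy[i, t, 1], label=i)
            for t in range(cfg.n_frames) for i in range(8)
        ]
        radius = 3 * np.sqrt(4 * 0.01 * 1.0)
        linked = trk.link_tracks(dets, radius)
        good = total = 0
        for tr in linked:
            for a, b in zip(tr.detections, tr.detections[1:]):
                total += 1
                good += a.label == b.label
        assert good / total >= 0.98


def _label_movie(boxes_by_frame):
    """Build a label stack from {frame: [(label, y_slice, x_slice), ...]}."""
    n = max(boxes_by_frame) + 1
    lab = np.zeros((n, 24, 24), np.int32)
    for t, boxes in boxes_by_frame.items():
        for label, ys, xs in boxes:
            lab[t, ys, xs] = label
    return lab


def _tracks_from_labels(lab, radius=6.0):
    dets = []
    for t in range(lab.shape[0]):
        for label in np.unique(lab[t])[1:]:
            ys, xs = np.nonzero(lab[t] == label)
            dets.append(_det(t, xs.mean(), ys.mean(), label=int(label),
                             area=float(len(xs))))
    return trk.link_tracks(dets, radius)


class TestEvents:
    def _merge_movie(self):
        boxes = {}
        for t in range(3):
            boxes[t] = [(1, slice(5, 8), slice(5, 8)), (2, slice(5, 8), slice(10, 13))]
        for t in range(3, 6):
            boxes[t] = [(1, slice(5, 8), slice(5, 13))]
        return _label_movie(boxes)

    def test_two_into_one_is_merging(self):
        lab = self._merge_movie()
        tracks = _tracks_from_labels(lab)
        events = trk.classify_events(tracks, lab)
        assert [e.event_type for e in events] == ["merging"]
        assert len(events[0].parents) == 2
        # both parents flagged for mobility exclusion
        excluded = {t.exclusion_reason for t in tracks if t.excluded}
        assert excluded == {"merge-contaminated"}

    def test_one_into_two_is_splitting(self):
        lab = self._merge_movie()[::-1]
        tracks = _tracks_from_labels(lab)
        events = trk.classify_events(tracks, lab)
        assert [e.event_type for e in events] == ["splitting"]
        assert len(events[0].children) == 2

    def test_merge_then_split_is_one_combined_event(self):
        boxes = {}
        for t in range(10):
            boxes[t] = [(1, slice(5, 8), slice(5, 8)), (2, slice(5, 8), slice(10, 13))]
        for t in range(10, 30):
            boxes[t] = [(1, slice(5, 8), slice(5, 13))]
        for t in range(30, 40):
            boxes[t] = [(1, slice(5, 8), slice(5, 8)), (2, slice(5, 8), slice(10, 13))]
        lab = _label_movie(boxes)
        tracks = _tracks_from_labels(lab)
        events = trk.classify_events(tracks, lab)
        assert [e.event_type for e in events] == ["merging_and_splitting"]
        assert events[0].frame == 10

    def test_time_reversal_swaps_merge_and_split_counts(self):
        lab = self._merge_movie()
        fwd = trk.raw_topology_events(lab)
        rev = trk.raw_topology_events(lab[::-1])
        count = lambda evs, kind: sum(e["type"] == kind for e in evs)
        assert count(fwd, "merging") == count(rev, "splitting")
        assert count(fwd, "splitting") == count(rev, "merging")

    def test_more_than_three_parents_unclassified(self):
        boxes = {0: [(k, slice(5, 8), slice(3 * k, 3 * k + 2)) for k in range(1, 6)],
                1: [(1, slice(5, 8), slice(3, 17))]}
        lab = _label_movie(boxes)
        tracks = _tracks_from_labels(lab, radius=10.0)
        events = trk.classify_events(tracks, lab)
        assert [e.event_type for e in events] == ["unclassified"]


class TestRatesAndFlags:
    def test_no_events_zero_fractions(self):
        tracks = [trk.FocusTrack(i, [_det(0, float(i), 0.0)]) for i in range(5)]
        summary = trk.event_rates([[]], [tracks])
        assert summary.loc["mean"].eq(0.0).all()

    def test_fraction_arithmetic(self):
        tracks = [trk.FocusTrack(i, [_det(0, float(i), 0.0)]) for i in range(20)]
        events = [
            trk.EventRecord("merging", 3, [0, 1], parents=[0, 1], children=[0]),
            trk.EventRecord("merging", 9, [2, 3], parents=[2, 3], children=[2]),
        ]
        summary = trk.event_rates([events], [tracks])
        assert summary.loc["mean", "merging"] == pytest.approx(4 / 20)

    def test_zero_focus_nucleus_skipped(self):
        tracks = [trk.FocusTrack(0, [_det(0, 0.0, 0.0)])]
        summary = trk.event_rates([[], []], [tracks, []])
        assert len(summary.attrs["per_nucleus"]) == 1
        with pytest.raises(ValueError):
            trk.event_rates([[]], [[]])

    def test_roi_migrant_flagged(self):
        inside = trk.FocusTrack(0, [_det(t, 1.0, 1.0) for t in range(5)])
        migrant = trk.FocusTrack(1, [_det(3, 9.0, 9.0, border=True)])
        trk.flag_roi_migrants([inside, migrant])
        assert not inside.excluded
        assert migrant.excluded and migrant.exclusion_reason == "roi-migrant"

    def test_every_exclusion_has_a_reason(self):
        lab = TestEvents()._merge_movie()
        tracks = _tracks_from_labels(lab)
        trk.classify_events(tracks, lab)
        trk.flag_roi_migrants(tracks)
        for tr in tracks:
            if tr.excluded:
                assert tr.exclusion_reason in {"merge-contaminated", "roi-migrant"}
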