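"""Focus tracking and merge/split event classification.

Per-frame detections are linked into tracks by nearest-neighbour
assignment (mutually nearest pairs first) within a linking radius, with
optional gap bridging. Interaction events are then classified from the
per-frame label images:

* **merging** — two or three labels at frame t spatially overlap a
  single label at t+1 (overlap at least ``overlap_fraction`` of the
  smaller label);
* **splitting** — the time-reverse: one label at t overlaps two or three
  labels at t+1;
* **merging_and_splitting** — a merge whose fused focus later splits
  within the observation window.

Events with four or more participants are logged but left unclassified.
Tracks touched by a merge are flagged ``excluded`` so they can be
dropped from mobility (MSD) analysis, as are tracks that migrate into
the nucleus ROI from the border after recording has started.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .segmentation import FocusDetection

__all__ = [
    "FocusTrack",
    "EventRecord",
    "link_tracks",
    "classify_events",
    "raw_topology_events",
    "event_rates",
    "tracks_to_dataframe",
    "events_to_json",
]


@dataclass
class FocusTrack:
    """Time-ordered detections of one focus identity."""

    track_id: int
    detections: list[FocusDetection] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None   # merge-contaminated | roi-migrant

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) positions in um on the track's own frame support."""
        return np.array([[d.x, d.y] for d in self.detections]).reshape(-1, 2)

    @property
    def gaps(self) -> int:
        f = self.frames
        return int((np.diff(f) - 1).sum()) if len(f) > 1 else 0

    def dense_positions(self, n_frames: int) -> np.ndarray:
        """(n_frames, 2) positions with NaN outside the track support."""
        out = np.full((n_frames, 2), np.nan)
        for d in self.detections:
            out[d.frame] = (d.x, d.y)
        return out

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason


@dataclass
class EventRecord:
    """One classified interaction event.

    ``parents`` are the track ids entering the event (the foci that
    merged, or the focus that split), ``children`` the tracks leaving it;
    ``track_ids`` is their union. The *foci that took part* in a merge
    are its parents and in a split its children — the fused blob itself
    may continue under a fresh track id, which would otherwise inflate
    participation counts.
    """

    event_type: str            # splitting | merging | merging_and_splitting | unclassified
    frame: int                 # frame at which the topology changes
    track_ids: list[int]
    parents: list[int] = field(default_factory=list)
    children: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        allowed = {"splitting", "merging", "merging_and_splitting", "unclassified"}
        if self.event_type not in allowed:
            raise ValueError(f"unknown event type {self.event_type!r}")

    def participating(self) -> set[int]:
        """Foci that took part: merge/merge-and-split -> the foci that
        came together (parents); split -> the foci that came apart
        (children)."""
        if self.event_type == "splitting":
            return set(self.children or self.track_ids)
        return set(self.parents or self.track_ids)


def link_tracks(
    detections: list[FocusDetection],
    linking_radius: float,
    max_gap: int = 1,
) -> list[FocusTrack]:
    """Link detections into tracks by conflict-free nearest neighbours.

    Frame by frame, candidate (track, detection) pairs within
    ``linking_radius`` (um, scaled by the gap length when bridging) are
    assigned in order of increasing distance, each track and detection at
    most once. Unassigned detections open new tracks; tracks unmatched
    for more than ``max_gap`` frames are closed.
    """
    if linking_radius <= 0:
        raise ValueError("linking_radius must be > 0")
    by_frame: dict[int, list[FocusDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []

    tracks: list[FocusTrack] = []
    active: list[FocusTrack] = []
    for frame in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(frame, [])
        # candidate links, nearest pairs first
        cands = []
        for ti, tr in enumerate(active):
            last = tr.detections[-1]
            gap = frame - last.frame
            if gap > max_gap + 1:
                continue
            for di, det in enumerate(dets):
                dist = float(np.hypot(det.x - last.x, det.y - last.y))
                if dist <= linking_radius * gap:
                    cands.append((dist, ti, di))
        cands.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            active[ti].detections.append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, det in enumerate(dets):
            if di not in used_d:
                tr = FocusTrack(track_id=len(tracks), detections=[det])
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active if frame - tr.detections[-1].frame <= max_gap]
    return tracks


def _overlap_pairs(
    lab_a: np.ndarray, lab_b: np.ndarray, overlap_fraction: float
) -> dict[tuple[int, int], int]:
    """Pixel-overlap counts for label pairs passing the fraction test."""
    both = (lab_a > 0) & (lab_b > 0)
    if not both.any():
        return {}
    pairs, counts = np.unique(
        np.stack([lab_a[both], lab_b[both]]), axis=1, return_counts=True
    )
    area_a = np.bincount(lab_a.ravel())
    area_b = np.bincount(lab_b.ravel())
    out = {}
    for (a, b), n in zip(pairs.T, counts):
        smaller = min(area_a[a], area_b[b])
        if n >= overlap_fraction * smaller:
            out[(int(a), int(b))] = int(n)
    return out


def raw_topology_events(
    label_images: np.ndarray, overlap_fraction: float = 0.3
) -> list[dict]:
    """Merge/split topology changes between consecutive label frames.

    A label at t+1 with >= 2 overlapping parents at t is a merge; a label
    at t with >= 2 overlapping children at t+1 is a split (the exact
    time-reverse, so reversing the stack swaps the two classes). Events
    are reported as dicts with the participating frame labels; track
    attribution and merge/split pairing happen in
    :func:`classify_events`.
    """
    events: list[dict] = []
    n = label_images.shape[0]
    for t in range(n - 1):
        ov = _overlap_pairs(label_images[t], label_images[t + 1], overlap_fraction)
        parents_of: dict[int, list[int]] = {}
        children_of: dict[int, list[int]] = {}
        for (a, b) in ov:
            parents_of.setdefault(b, []).append(a)
            children_of.setdefault(a, []).append(b)
        for b, parents in parents_of.items():
            if len(parents) >= 2:
                events.append({"type": "merging", "frame": t + 1,
                               "parent_labels": sorted(parents), "child_label": b})
        for a, children in children_of.items():
            if len(children) >= 2:
                events.append({"type": "splitting", "frame": t + 1,
                               "parent_label": a, "child_labels": sorted(children)})
    return events


def classify_events(
    tracks: list[FocusTrack],
    label_images: np.ndarray,
    overlap_fraction: float = 0.3,
) -> list[EventRecord]:
    """Classify merge/split/merge-and-split events and flag tracks.

    Raw topology changes are mapped onto track identities; a merge
    followed by a later split of the fused focus is reclassified as one
    ``merging_and_splitting`` event. Events with more than three participants fall outside the
    two-or-three-foci classification scheme and come back ``unclassified``.
    All tracks participating in a merge (either side) are flagged
    ``excluded`` (merge-contaminated) for mobility analysis.
    """
    # (frame, label) -> track id
    owner: dict[tuple[int, int], int] = {}
    for tr in tracks:
        for d in tr.detections:
            owner[(d.frame, d.label)] = tr.track_id
    track_by_id = {tr.track_id: tr for tr in tracks}

    raw = raw_topology_events(label_images, overlap_fraction)
    merges: list[EventRecord] = []
    splits: list[EventRecord] = []
    unclassified: list[EventRecord] = []
    # fused-track id -> index into merges, for later pairing
    fused_owner: dict[int, int] = {}

    for ev in raw:
        t = ev["frame"]
        if ev["type"] == "merging":
            parent_ids = sorted({
                owner.get((t - 1, a)) for a in ev["parent_labels"]
                if owner.get((t - 1, a)) is not None
            })
            child_id = owner.get((t, ev["child_label"]))
            ids = [i for i in parent_ids if i is not None]
            if child_id is not None and child_id not in ids:
                ids = ids + [child_id]
            if len(ev["parent_labels"]) > 3:
                unclassified.append(EventRecord("unclassified", t, ids))
                continue
            rec = EventRecord("merging", t, ids, parents=parent_ids,
                              children=[child_id] if child_id is not None else [])
            merges.append(rec)
            if child_id is not None:
                fused_owner[child_id] = len(merges) - 1
            for i in ids:
                if i in track_by_id:
                    track_by_id[i].exclude("merge-contaminated")
        else:
            parent_id = owner.get((t - 1, ev["parent_label"]))
            child_ids = sorted({
                owner.get((t, b)) for b in ev["child_labels"]
                if owner.get((t, b)) is not None
            })
            ids = ([parent_id] if parent_id is not None else []) + \
                  [i for i in child_ids if i != parent_id]
            if len(ev["child_labels"]) > 3:
                unclassified.append(EventRecord("unclassified", t, ids))
                continue
            splits.append(EventRecord(
                "splitting", t, ids,
                parents=[parent_id] if parent_id is not None else [],
                children=child_ids))

    # pair each merge with a later split of the same fused track
    paired_m: set[int] = set()
    paired_s: set[int] = set()
    combined: list[EventRecord] = []
    for si, s in enumerate(splits):
        cand = [
            (mi, m) for mi, m in enumerate(merges)
            if mi not in paired_m and m.frame < s.frame
            and set(m.track_ids) & set(s.track_ids)
        ]
        if cand:
            mi, m = cand[0]
            paired_m.add(mi)
            paired_s.add(si)
            ids = sorted(set(m.track_ids) | set(s.track_ids))
            combined.append(EventRecord(
                "merging_and_splitting", m.frame, ids,
                parents=m.parents, children=s.children))

    out = (
        [m for i, m in enumerate(merges) if i not in paired_m]
        + [s for i, s in enumerate(splits) if i not in paired_s]
        + combined + unclassified
    )
    out.sort(key=lambda e: e.frame)
    return out


def flag_roi_migrants(
    tracks: list[FocusTrack], first_frame: int = 0
) -> list[FocusTrack]:
    """Flag tracks that enter at the ROI border after recording starts.

    A track whose first detection appears after ``first_frame`` touching
    the nucleus border is treated as an external focus drifting into the
    ROI and excluded from mobility analysis.
    """
    for tr in tracks:
        if tr.excluded or not tr.detections:
            continue
        first = tr.detections[0]
        if first.frame > first_frame and first.touches_border:
            tr.exclude("roi-migrant")
    return tracks


def event_rates(
    events_per_nucleus: list[list[EventRecord]],
    tracks_per_nucleus: list[list[FocusTrack]],
) -> pd.DataFrame:
    """Per-nucleus fractions of foci in each event class, mean +/- SD.

    The fraction divides the number of foci (tracks) participating in an
    event class by the total foci in the nucleus. Nuclei with zero foci
    are skipped.
    """
    rows = []
    for events, tracks in zip(events_per_nucleus, tracks_per_nucleus):
        # a track that begins at an event frame as one of its children is
        # the continuation of existing foci (a fused blob, or a re-separated
        # focus), not a new focus identity
        first_frame = {tr.track_id: (tr.detections[0].frame if tr.detections else -1)
                       for tr in tracks}
        continuations: set[int] = set()
        for ev in events:
            for c in ev.children:
                if first_frame.get(c, -1) >= ev.frame:
                    continuations.add(c)
        n = len(tracks) - len(continuations)
        if n <= 0:
            continue
        by_class: dict[str, set[int]] = {
            "merging": set(), "splitting": set(), "merging_and_splitting": set()}
        for ev in events:
            if ev.event_type in by_class:
                by_class[ev.event_type].update(ev.participating())
        rows.append({
            "n_foci": n,
            "merging": len(by_class["merging"]) / n,
            "splitting": len(by_class["splitting"]) / n,
            "merging_and_splitting": len(by_class["merging_and_splitting"]) / n,
        })
    if not rows:
        raise ValueError("no nuclei with foci")
    df = pd.DataFrame(rows)
    summary = df[["merging", "splitting", "merging_and_splitting"]].agg(["mean", "std"])
    summary.attrs["per_nucleus"] = df
    return summary


def tracks_to_dataframe(tracks: list[FocusTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for d in tr.detections:
            rows.append((tr.track_id, d.frame, d.x, d.y, d.area,
                         d.mean_intensity, tr.excluded, tr.exclusion_reason or ""))
    return pd.DataFrame(rows, columns=[
        "track_id", "frame", "x_um", "y_um", "area_um2", "mean_intensity",
        "excluded", "reason"])


def events_to_json(events: list[EventRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"type": e.event_type, "frame": e.frame, "track_ids": e.track_ids}
             for e in events], fh, indent=1)
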