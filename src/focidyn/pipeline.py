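"""End-to-end orchestration: simulate or load stacks, then analyse.

``analyze_stack`` runs the full per-nucleus chain (registration ->
nucleus ROI -> focus detection -> tracking -> event classification);
``run_condition`` repeats it over several simulated nuclei of one
irradiation condition and pools the per-nucleus outputs the statistics
modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import registration as reg
from . import segmentation as seg
from . import tracking as trk
from .synthetic import GroundTruth, SimulationConfig, TimeLapseStack, simulate_nucleus

__all__ = ["NucleusAnalysis", "ConditionResult", "analyze_stack", "run_condition",
           "default_linking_radius"]


def default_linking_radius(config: SimulationConfig) -> float:
    """Three times the RMS free-diffusion step, floored for slow foci."""
    return max(3.0 * np.sqrt(4.0 * config.Dc * config.frame_interval), 0.5)


@dataclass
class NucleusAnalysis:
    """Everything the pipeline measured in one nucleus."""

    transforms: list[reg.RigidTransform]
    registered: TimeLapseStack
    roi: seg.NucleusROI
    detections: list[seg.FocusDetection]
    labels: np.ndarray
    tracks: list[trk.FocusTrack]
    events: list[trk.EventRecord]
    fpc: np.ndarray
    truth: GroundTruth | None = None

    def mean_focus_stat(self, attr: str) -> np.ndarray:
        """Per-frame mean of a detection attribute (area, mean_intensity).

        NaN on frames without detections.
        """
        n = self.registered.n_frames
        sums = np.zeros(n)
        counts = np.zeros(n)
        for d in self.detections:
            sums[d.frame] += getattr(d, attr)
            counts[d.frame] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def analyze_stack(
    stack: TimeLapseStack,
    seg_params: seg.SegmentationParams | None = None,
    linking_radius: float = 0.6,
    max_gap: int = 1,
    overlap_fraction: float = 0.3,
    register: bool = True,
    truth: GroundTruth | None = None,
) -> NucleusAnalysis:
    """Registration -> ROI -> detection -> tracking -> events for one stack."""
    seg_params = seg_params or seg.SegmentationParams()
    if register:
        transforms = reg.estimate_rigid(stack)
        registered = reg.apply_rigid(stack, transforms)
    else:
        transforms = [reg.RigidTransform(t, 0.0, 0.0, 0.0)
                      for t in range(stack.n_frames)]
        registered = stack
    roi = seg.extract_nucleus_roi(registered, seg_params)
    detections, labels = seg.detect_stack(registered, roi, seg_params)
    fpc = seg.measure_fpc(detections, registered.n_frames)
    tracks = trk.link_tracks(detections, linking_radius, max_gap=max_gap)
    events = trk.classify_events(tracks, labels, overlap_fraction)
    trk.flag_roi_migrants(tracks)
    return NucleusAnalysis(
        transforms=transforms, registered=registered, roi=roi,
        detections=detections, labels=labels, tracks=tracks, events=events,
        fpc=fpc, truth=truth,
    )


@dataclass
class ConditionResult:
    """Pooled per-nucleus outputs for one irradiation condition."""

    condition: str
    analyses: list[NucleusAnalysis] = field(default_factory=list)

    @property
    def fpc_matrix(self) -> np.ndarray:
        return np.stack([a.fpc for a in self.analyses])

    def pooled_tracks(self) -> list[trk.FocusTrack]:
        out = []
        for a in self.analyses:
            out.extend(a.tracks)
        return out

    def mean_stat_matrix(self, attr: str) -> np.ndarray:
        return np.stack([a.mean_focus_stat(attr) for a in self.analyses])


def run_condition(
    config: SimulationConfig,
    n_nuclei: int,
    base_seed: int = 0,
    register: bool = True,
    seg_params: seg.SegmentationParams | None = None,
) -> ConditionResult:
    """Simulate and analyse ``n_nuclei`` recordings of one condition.

    Nucleus ``i`` uses seed ``base_seed + i`` so runs are reproducible
    and nuclei independent.
    """
    result = ConditionResult(condition=config.condition)
    radius = default_linking_radius(config)
    for i in range(n_nuclei):
        cfg = replace(config, seed=int(base_seed + i))
        stack, truth = simulate_nucleus(cfg)
        analysis = analyze_stack(
            stack, seg_params=seg_params, linking_radius=radius,
            register=register and any(cfg.drift_per_frame), truth=truth,
        )
        result.analyses.append(analysis)
    return result
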