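"""Rigid-body stabilisation of whole-nucleus motion.

Nuclei translate and rotate during a time-lapse recording; focus motion
can only be interpreted once that whole-nucleus motion is removed. Each
frame is registered to a reference frame with a rigid (translation +
rotation) transform so that residual focus motion is intranuclear.

Estimation is sequential: each frame is registered to its predecessor
(phase cross-correlation for the shift, a coarse grid plus bounded local
search for the rotation angle) and the pairwise transforms are composed
back to the reference frame. Application warps each frame by its
transform with bilinear interpolation; out-of-field pixels are filled
with the median border intensity.

Convention: a :class:`RigidTransform` describes the *motion* of a frame
relative to the reference — content at point ``p`` in the reference
appears at ``R_theta(p - c) + c + (dx, dy)`` in the frame (``c`` = image
centre, x = column, y = row, theta counter-clockwise in the array sense).
:func:`apply_rigid` undoes that motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from skimage.registration import phase_cross_correlation
from skimage.transform import EuclideanTransform, warp

__all__ = [
    "RigidTransform",
    "euclidean_about_center",
    "estimate_rigid",
    "apply_rigid",
    "transforms_to_csv",
    "transforms_from_csv",
]

_MIN_CONFIDENCE = 0.5  # NCC below this marks a transform low-confidence


@dataclass
class RigidTransform:
    """Motion of one frame relative to the reference frame.

    ``dx``/``dy`` in pixels, ``theta`` in degrees. The reference frame
    carries the identity. ``low_confidence`` marks frames whose content
    could not support the estimate (blank or pure-noise frames).
    """

    frame_index: int
    dx: float
    dy: float
    theta: float
    low_confidence: bool = False

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.dx) < tol and abs(self.dy) < tol and abs(self.theta) < tol


def euclidean_about_center(
    dx: float, dy: float, theta_deg: float, center: tuple[float, float]
) -> EuclideanTransform:
    """Rigid map p -> R_theta(p - c) + c + (dx, dy), coordinates (x, y)."""
    cx, cy = center
    shift_to = EuclideanTransform(translation=(-cx, -cy))
    rot = EuclideanTransform(rotation=np.deg2rad(theta_deg))
    shift_back = EuclideanTransform(translation=(cx + dx, cy + dy))
    return EuclideanTransform(matrix=shift_back.params @ rot.params @ shift_to.params)


def _decompose_about_center(
    matrix: np.ndarray, center: tuple[float, float]
) -> tuple[float, float, float]:
    """Recover (dx, dy, theta_deg) in the about-centre convention."""
    theta = np.rad2deg(np.arctan2(matrix[1, 0], matrix[0, 0]))
    cx, cy = center
    moved_center = matrix @ np.array([cx, cy, 1.0])
    return float(moved_center[0] - cx), float(moved_center[1] - cy), float(theta)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _register_pair(
    ref: np.ndarray,
    mov: np.ndarray,
    theta_max: float,
    upsample: int = 20,
    theta_center: float = 0.0,
) -> tuple[float, float, float, float]:
    """Estimate the motion (dx, dy, theta) of ``mov`` relative to ``ref``.

    For a candidate rotation theta (searched in ``theta_center`` +/-
    ``theta_max``), ``mov`` resampled through the pure rotation differs
    from ``ref`` by a pure shift, which phase cross-correlation measures
    to subpixel precision; the candidate is scored by the NCC between
    ``ref`` and ``mov`` warped back by the full transform. Returns
    (dx, dy, theta, ncc at the optimum).
    """
    center = ((ref.shape[1] - 1) / 2.0, (ref.shape[0] - 1) / 2.0)
    cval = float(np.median(mov))

    def eval_theta(theta: float) -> tuple[float, float, float]:
        if theta:
            rot = euclidean_about_center(0.0, 0.0, theta, center)
            unrot = warp(mov, rot, order=1, mode="constant",
                         cval=cval, preserve_range=True)
        else:
            unrot = mov
        shift, _, _ = phase_cross_correlation(
            ref, unrot, upsample_factor=upsample, normalization=None)
        dy_pc, dx_pc = float(shift[0]), float(shift[1])
        rad = np.deg2rad(theta)
        rot_m = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        tx, ty = -(rot_m @ np.array([dx_pc, dy_pc]))
        full = euclidean_about_center(tx, ty, theta, center)
        back = warp(mov, full, order=1, mode="constant",
                    cval=cval, preserve_range=True)
        return tx, ty, _ncc(ref, back)

    step = max(theta_max / 4.0, 0.5) if theta_max > 0 else 1.0
    coarse = (theta_center + np.arange(-theta_max, theta_max + 1e-9, step)
              if theta_max > 0 else np.array([theta_center]))
    best: tuple[float, float, float, float] | None = None
    for th in coarse:
        tx, ty, sc = eval_theta(float(th))
        if best is None or sc > best[3]:
            best = (tx, ty, float(th), sc)

    if theta_max > 0:
        th0 = best[2]

        def neg(th: float) -> float:
            return -eval_theta(float(th))[2]

        res = minimize_scalar(neg, bounds=(th0 - step, th0 + step),
                              method="bounded", options={"xatol": 0.02})
        tx, ty, sc = eval_theta(float(res.x))
        if sc > best[3]:
            best = (tx, ty, float(res.x), sc)
    return best


def estimate_rigid(
    stack,
    reference_frame: int = 0,
    theta_max: float = 4.0,
    upsample: int = 20,
    refine_to_reference: bool = True,
) -> list[RigidTransform]:
    """Per-frame rigid motion relative to the reference frame.

    Consecutive frame pairs are registered and the pairwise motions
    composed (chained) out to the reference, which keeps each individual
    search window small. Because chaining lets small pairwise errors
    accumulate over long recordings, each frame is then re-registered
    directly against the reference frame in a narrow window around the
    chained estimate (``refine_to_reference``). Blank frames inherit the
    neighbouring estimate and are flagged ``low_confidence``, as are
    frames whose correlation optimum is weak (pure noise).

    Parameters
    ----------
    stack : TimeLapseStack or (n_frames, H, W) array
    reference_frame : int
        Frame that receives the identity transform.
    theta_max : float
        Half-width (degrees) of the pairwise rotation search window.
    upsample : int
        Phase-correlation upsampling (subpixel resolution 1/upsample px).
    refine_to_reference : bool
        Re-register each frame to the reference around the chained
        estimate, removing cumulative drift of the estimate itself.
    """
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    if not (0 <= reference_frame < n):
        raise ValueError("reference_frame out of range")
    h, w = data.shape[1:]
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    results: dict[int, tuple[np.ndarray, bool]] = {reference_frame: (np.eye(3), False)}
    order = list(range(reference_frame + 1, n)) + list(range(reference_frame - 1, -1, -1))
    for idx in order:
        prev = idx - 1 if idx > reference_frame else idx + 1
        ref_img, mov_img = data[prev], data[idx]
        if ref_img.std() < 1e-9 or mov_img.std() < 1e-9:
            results[idx] = (results[prev][0].copy(), True)
            continue
        tx, ty, th, sc = _register_pair(ref_img, mov_img, theta_max, upsample)
        pair = euclidean_about_center(tx, ty, th, center).params
        results[idx] = (pair @ results[prev][0], sc < _MIN_CONFIDENCE)

    # confidence is a pair property: a reference frame whose neighbour
    # could not be matched (e.g. pure noise) is itself unreliable
    neighbour = reference_frame + 1 if reference_frame + 1 < n else reference_frame - 1
    results[reference_frame] = (np.eye(3), results[neighbour][1])

    if refine_to_reference:
        ref_img = data[reference_frame]
        for idx in range(n):
            if idx == reference_frame or results[idx][1]:
                continue
            mov_img = data[idx]
            if ref_img.std() < 1e-9 or mov_img.std() < 1e-9:
                continue
            _, _, th0 = _decompose_about_center(results[idx][0], center)
            tx, ty, th, sc = _register_pair(
                ref_img, mov_img, theta_max=1.0, upsample=upsample,
                theta_center=th0)
            if sc >= _MIN_CONFIDENCE:
                results[idx] = (euclidean_about_center(tx, ty, th, center).params,
                                False)

    out = []
    for idx in range(n):
        mat, low = results[idx]
        dx, dy, th = _decompose_about_center(mat, center)
        out.append(RigidTransform(frame_index=idx, dx=dx, dy=dy, theta=th,
                                  low_confidence=low))
    return out


def apply_rigid(stack, transforms: list[RigidTransform]):
    """Undo the estimated motion: returns the registered stack.

    ``registered(p) = frame(M(p))`` where ``M`` is the frame's motion
    transform, so drifted content returns to its reference position.
    Bilinear interpolation; out-of-field pixels filled with the frame's
    median border intensity; identity transforms leave frames bit-exact.
    """
    from .synthetic import TimeLapseStack  # local import avoids a cycle

    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    if len(transforms) != data.shape[0]:
        raise ValueError(f"got {len(transforms)} transforms for {data.shape[0]} frames")
    h, w = data.shape[1:]
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    out = np.empty_like(data, dtype=np.float32)
    for t, tf in enumerate(transforms):
        frame = data[t]
        if tf.is_identity():
            out[t] = frame
            continue
        border = np.concatenate([frame[0], frame[-1], frame[:, 0], frame[:, -1]])
        cval = float(np.median(border))
        fwd = euclidean_about_center(tf.dx, tf.dy, tf.theta, center)
        out[t] = warp(frame, fwd, order=1, mode="constant",
                      cval=cval, preserve_range=True)
    if hasattr(stack, "pixel_size"):
        return TimeLapseStack(data=out, pixel_size=stack.pixel_size,
                              frame_interval=stack.frame_interval)
    return out


def transforms_to_csv(transforms: list[RigidTransform], path) -> None:
    pd.DataFrame(
        [(t.frame_index, t.dx, t.dy, t.theta, t.low_confidence) for t in transforms],
        columns=["frame", "dx", "dy", "theta_deg", "low_confidence"],
    ).to_csv(path, index=False)


def transforms_from_csv(path) -> list[RigidTransform]:
    df = pd.read_csv(path)
    return [
        RigidTransform(int(r.frame), float(r.dx), float(r.dy),
                       float(r.theta_deg), bool(r.low_confidence))
        for r in df.itertuples()
    ]
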