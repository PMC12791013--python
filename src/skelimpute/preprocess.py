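"""Per-sample normalization: view-invariant rotation and min-max scaling.

The rotation translates a sample by the body barycenter of its middle frame
and rotates about the z axis so the middle-frame heading aligns with the
(x=1, y=0) direction.  This removes absolute position and orientation so a
model can focus on intrinsic motion.  Min-max scaling then maps every axis to
[-1, 1] using the observed coordinates of the sample.  Both transforms store
their parameters in a :class:`TransformMeta` so imputations made in
normalized space can be mapped back exactly to original units.

Composition order: ``apply = minmax o rotate``; the inverse un-scales, then
un-rotates, then un-translates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ShapeError
from .io import Sample


@dataclass
class HeadingRule:
    """How the middle-frame heading vector is defined.

    mode='pair': vector from keypoint ``pair[0]`` to ``pair[1]`` in the x-y
    plane (e.g. tail -> head).  mode='principal_axis': first principal axis of
    the middle-frame x-y keypoint cloud; since a principal axis has no
    intrinsic sign, the sign is fixed so that the component of largest
    magnitude is positive.
    """

    mode: str = "principal_axis"
    pair: Optional[tuple[int, int]] = None


@dataclass
class TransformMeta:
    """Parameters of the rotate + min-max transform; enables the exact inverse."""

    barycenter: np.ndarray | None = None       # (D,) original units
    rotation_angle: float = 0.0                # radians about z
    per_axis_min: np.ndarray | None = None     # (D,)
    per_axis_max: np.ndarray | None = None     # (D,)
    degenerate_heading: bool = False

    def copy(self) -> "TransformMeta":
        return TransformMeta(
            None if self.barycenter is None else self.barycenter.copy(),
            self.rotation_angle,
            None if self.per_axis_min is None else self.per_axis_min.copy(),
            None if self.per_axis_max is None else self.per_axis_max.copy(),
            self.degenerate_heading)


def _rotate_xy(coords: np.ndarray, angle: float) -> np.ndarray:
    """Rotate the x-y plane of (..., D) coordinates by ``angle`` radians."""
    out = coords.copy()
    c, s = np.cos(angle), np.sin(angle)
    x, y = coords[..., 0], coords[..., 1]
    out[..., 0] = c * x - s * y
    out[..., 1] = s * x + c * y
    return out


def heading_vector(coords_mid: np.ndarray, observed: np.ndarray,
                   rule: HeadingRule) -> np.ndarray | None:
    """Middle-frame heading in the x-y plane, or None when degenerate."""
    if rule.mode == "pair" and rule.pair is not None:
        a, b = rule.pair
        if observed[a] and observed[b]:
            v = coords_mid[b, :2] - coords_mid[a, :2]
            return v if np.linalg.norm(v) > 1e-12 else None
        # masked pair endpoint: fall back to the principal axis
    xy = coords_mid[observed][:, :2]
    if xy.shape[0] < 2:
        return None
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    w, vecs = np.linalg.eigh(cov)
    if w[-1] < 1e-24:
        return None
    v = vecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:  # sign convention (eigenvectors are +/-)
        v = -v
    return v


def view_invariant_rotate(sample: Sample,
                          heading_rule: HeadingRule | None = None
                          ) -> tuple[Sample, TransformMeta]:
    """Translate by the middle-frame barycenter and align the heading with +x.

    The same translation and z-rotation are applied to every frame and
    keypoint.  The barycenter uses all observed keypoints of the middle frame
    (index L//2).  A zero-length heading falls back to the identity rotation,
    flagged in ``meta.degenerate_heading``.
    """
    rule = heading_rule or HeadingRule()
    coords = sample.coords
    L = coords.shape[0]
    mid = L // 2
    observed = ~sample.missing[mid]
    if not observed.any():
        # no anchor in the middle frame: use the sample-wide barycenter
        bary = np.nanmean(coords.reshape(-1, coords.shape[2]), axis=0)
        degenerate = True
        angle = 0.0
    else:
        bary = coords[mid][observed].mean(axis=0)
        v = heading_vector(coords[mid] - bary, observed, rule)
        if v is None:
            degenerate, angle = True, 0.0
        else:
            degenerate = False
            angle = -float(np.arctan2(v[1], v[0]))
    out = _rotate_xy(coords - bary, angle)
    meta = TransformMeta(barycenter=bary.copy(), rotation_angle=angle,
                         degenerate_heading=degenerate)
    return Sample(sample.recording_id, sample.start_frame, out,
                  sample.missing.copy(), meta), meta


def minmax_normalize(sample: Sample,
                     meta: TransformMeta | None = None
                     ) -> tuple[Sample, TransformMeta]:
    """Map each axis to [-1, 1] over the observed cells of the sample.

    out = 2 (x - min_a) / (max_a - min_a) - 1 per axis a.  NaN cells stay
    NaN.  A static axis (max == min) maps to 0 and the inverse returns the
    stored constant, keeping the round trip well defined.  Scaling must be
    computed before any artificial masking so inserted gaps cannot influence
    the ground-truth scale.
    """
    coords = sample.coords
    D = coords.shape[2]
    flat = coords.reshape(-1, D)
    with np.errstate(all="ignore"):
        mn = np.nanmin(flat, axis=0)
        mx = np.nanmax(flat, axis=0)
    span = mx - mn
    out = np.empty_like(coords)
    for d in range(D):
        if span[d] > 0:
            out[..., d] = 2.0 * (coords[..., d] - mn[d]) / span[d] - 1.0
        else:
            out[..., d] = np.where(np.isnan(coords[..., d]), np.nan, 0.0)
    meta = meta.copy() if meta is not None else TransformMeta()
    meta.per_axis_min, meta.per_axis_max = mn, mx
    return Sample(sample.recording_id, sample.start_frame, out,
                  sample.missing.copy(), meta), meta


def normalize_sample(sample: Sample,
                     heading_rule: HeadingRule | None = None
                     ) -> tuple[Sample, TransformMeta]:
    """Rotate then min-max normalize; returns the combined TransformMeta."""
    rotated, meta = view_invariant_rotate(sample, heading_rule)
    return minmax_normalize(rotated, meta)


def inverse_transform(sample: Sample, meta: TransformMeta) -> Sample:
    """Exact inverse of ``normalize_sample`` (or of either transform alone)."""
    coords = sample.coords
    out = coords.copy()
    D = coords.shape[2]
    if meta.per_axis_min is not None:
        if meta.per_axis_min.shape != (D,):
            raise ShapeError("TransformMeta dimensionality does not match sample")
        span = meta.per_axis_max - meta.per_axis_min
        for d in range(D):
            if span[d] > 0:
                out[..., d] = (coords[..., d] + 1.0) / 2.0 * span[d] + meta.per_axis_min[d]
            else:
                out[..., d] = np.where(np.isnan(coords[..., d]), np.nan,
                                       meta.per_axis_min[d])
    if meta.barycenter is not None:
        if meta.barycenter.shape != (D,):
            raise ShapeError("TransformMeta dimensionality does not match sample")
        out = _rotate_xy(out, -meta.rotation_angle) + meta.barycenter
    return Sample(sample.recording_id, sample.start_frame, out,
                  sample.missing.copy(), None)
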