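"""Evaluation metrics on masked cells, plus per-sample motion descriptors.

All imputation metrics are computed only on the masked keypoint-frames; the
normalizer N counts masked (frame, keypoint) positions, not scalar
coordinates.  Reported comparisons between methods are made in original
units after inverse transformation.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from .errors import EmptyInputError, UndefinedMetricError
from .io import Recording, Sample


def _sq_dists(pred: np.ndarray, gt: np.ndarray, gap_mask: np.ndarray
              ) -> np.ndarray:
    """Squared Euclidean error per masked keypoint-frame (1D array)."""
    mask = np.asarray(gap_mask, dtype=bool)
    if mask.sum() == 0:
        raise UndefinedMetricError("no masked cells (N = 0)")
    d2 = ((np.asarray(pred) - np.asarray(gt)) ** 2).sum(axis=-1)
    return d2[mask]


def rmse(pred: np.ndarray, gt: np.ndarray, gap_mask: np.ndarray) -> float:
    """sqrt(1/N sum over masked (k, t) of squared coordinate error)."""
    return float(np.sqrt(_sq_dists(pred, gt, gap_mask).mean()))


def mpjpe(pred: np.ndarray, gt: np.ndarray, gap_mask: np.ndarray) -> float:
    """Mean per-joint position error: 1/N sum of Euclidean distances."""
    return float(np.sqrt(_sq_dists(pred, gt, gap_mask)).mean())


def pck(pred: np.ndarray, gt: np.ndarray, gap_mask: np.ndarray,
        th: float = 0.01, max_dist: float = 1.0) -> float:
    """Fraction of masked points with error < th * max_dist.

    ``max_dist`` is the dataset-wide maximum inter-keypoint distance; the
    default threshold th = 0.01 corresponds to 1% of it.
    """
    if max_dist <= 0:
        raise UndefinedMetricError("max_dist must be positive")
    d = np.sqrt(_sq_dists(pred, gt, gap_mask))
    return float((d < th * max_dist).mean())


def max_interkeypoint_distance(recordings: list[Recording]) -> float:
    """Maximum distance between two observed keypoints within any frame."""
    best = -np.inf
    for rec in recordings:
        c = rec.coords
        diffs = c[:, :, None, :] - c[:, None, :, :]       # (T, K, K, D)
        d2 = (diffs ** 2).sum(axis=-1)
        if not np.all(np.isnan(d2)):
            best = max(best, float(np.sqrt(np.nanmax(d2))))
    if not np.isfinite(best) or best <= 0:
        raise EmptyInputError("no frame with two observed keypoints")
    return best


def movement(sample: Sample) -> float:
    """Averaged absolute frame-to-frame difference of every coordinate.

    Defined on complete samples only.
    """
    if not sample.is_complete:
        raise EmptyInputError("movement is defined on complete samples")
    if sample.length < 2:
        raise EmptyInputError("need at least 2 frames")
    return float(np.abs(np.diff(sample.coords, axis=0)).mean())


def periodicity(sample: Sample) -> float:
    """Largest single-frequency weight in the Fourier spectrum of any
    coordinate series, over all keypoints and axes.

    The DC component is excluded (otherwise any offset would dominate), and
    magnitudes are scaled by 2/L so a pure sinusoid of amplitude a scores a.
    """
    if not sample.is_complete:
        raise EmptyInputError("periodicity is defined on complete samples")
    L = sample.length
    series = sample.coords.reshape(L, -1)
    spec = np.abs(scipy.fft.rfft(series, axis=0))[1:]  # drop DC
    if spec.size == 0:
        return 0.0
    return float(spec.max() * 2.0 / L)
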