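"""Full-recording imputation, uncertainty filtering and the linear baseline.

A recording is tiled into windows centered on its native gaps.  Each window
is normalized (rotation + min-max from observed cells), passed through the
model, inverse-transformed, and its imputations written back — but only when
the window is accepted: windows whose per-keypoint gap runs exceed L-2
frames, with too many simultaneously missing keypoints, or (probabilistic
models) whose estimated error exceeds the threshold contribute nothing.
Observed coordinates are never altered.  Cells covered by several accepted
windows are averaged, inverse-variance weighted when deviations are
available.

The estimated error of a window is the mean predicted standard deviation
over its masked cells (normalized units); thresholding on it trades coverage
for accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ShapeError
from .gaps import missing_runs
from .io import Recording, Sample
from .nn.models import Prediction, _ImputerBase, predict_batch
from .preprocess import HeadingRule, inverse_transform, normalize_sample


@dataclass
class WindowReport:
    start: int
    estimated_error: float | None
    accepted: bool
    reason: str = ""


@dataclass
class ImputedRecording:
    """Recording with imputations substituted at (some) missing cells."""

    coords: np.ndarray            # (T, K, D)
    still_missing: np.ndarray     # (T, K) bool
    per_window_error: list[WindowReport] = field(default_factory=list)


# ---------------------------------------------------------------------------


def linear_interpolate_array(coords: np.ndarray, missing: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation on a (T, K, D) array; returns (filled coords,
    still-missing mask).  Leading/trailing gaps (no anchor on one side) are
    left missing."""
    T, K, D = coords.shape
    out = coords.copy()
    still = missing.copy()
    idx = np.arange(T)
    for k in range(K):
        obs = ~missing[:, k]
        if obs.sum() < 2:
            continue
        first, last = idx[obs][0], idx[obs][-1]
        interior = missing[:, k] & (idx > first) & (idx < last)
        if not interior.any():
            continue
        for d in range(D):
            out[interior, k, d] = np.interp(idx[interior], idx[obs],
                                            coords[obs, k, d])
        still[interior, k] = False
    return out, still


def linear_interpolate(recording: Recording) -> ImputedRecording:
    """Per-keypoint, per-axis linear interpolation across interior gaps.

    The baseline widely used in behavioral pipelines; exact on linear motion,
    poor on oscillatory motion once gaps span a sizable fraction of a cycle.
    """
    coords, still = linear_interpolate_array(recording.coords, recording.missing)
    return ImputedRecording(coords, still)


def estimated_error(prediction: Prediction, gap_mask: np.ndarray) -> float:
    """Mean predicted standard deviation over masked cells (normalized
    units) — the per-sample confidence proxy."""
    if prediction.std is None:
        raise ConfigError("estimated error requires a probabilistic model")
    mask = np.asarray(gap_mask, dtype=bool)
    if mask.sum() == 0:
        raise ConfigError("no masked cells")
    return float(prediction.std[mask].mean())


def filter_by_error(results: list[tuple[object, float]],
                    threshold: float) -> list[tuple[object, float]]:
    """Keep samples whose estimated error is <= threshold."""
    return [(s, e) for s, e in results if e <= threshold]


# ---------------------------------------------------------------------------


def _plan_windows(missing: np.ndarray, L: int) -> tuple[list[int], np.ndarray]:
    """Choose window starts centering each native gap; mark cells of runs
    longer than L-2 as not imputable."""
    T, K = missing.shape
    imputable = np.zeros((T, K), dtype=bool)
    starts: set[int] = set()
    for k in range(K):
        for s, n in missing_runs(missing[:, k]):
            if n > L - 2:
                continue  # prohibitively long gap
            imputable[s:s + n, k] = True
            w = int(np.clip(s + n // 2 - L // 2, 0, T - L))
            starts.add(w)
    return sorted(starts), imputable


def impute_recording(model: _ImputerBase,
                     recording: Recording,
                     L: int | None = None,
                     error_threshold: float = 0.1,
                     max_simultaneous: int | None = None,
                     heading_rule: HeadingRule | None = None,
                     batch_size: int = 32) -> ImputedRecording:
    """Impute every native gap a trained model can cover.

    ``max_simultaneous`` caps the number of distinct missing keypoints per
    window (defaults to the gap regime the model was trained for);
    ``error_threshold`` applies to probabilistic models only.
    """
    c = model.config
    L = L if L is not None else c.L
    if recording.n_keypoints != c.K or recording.dims != c.D or L != c.L:
        raise ShapeError("model configuration does not match the recording")
    if max_simultaneous is None:
        max_simultaneous = c.n_missing_train
    T = recording.n_frames
    coords_out = recording.coords.copy()
    reports: list[WindowReport] = []
    if T < L or not recording.missing.any():
        return ImputedRecording(coords_out, recording.missing.copy(), reports)

    starts, imputable = _plan_windows(recording.missing, L)
    acc = np.zeros((T, c.K, c.D))
    wsum = np.zeros((T, c.K))

    pending: list[tuple[int, Sample, np.ndarray]] = []
    for w in starts:
        win_missing = recording.missing[w:w + L]
        target_cells = imputable[w:w + L] & win_missing
        if not target_cells.any():
            continue
        n_sim = int(win_missing.any(axis=0).sum())
        if n_sim > max_simultaneous:
            reports.append(WindowReport(w, None, False, "too_many_missing"))
            continue
        sample = Sample(recording.id, w, recording.coords[w:w + L].copy(),
                        win_missing.copy())
        norm, meta = normalize_sample(sample, heading_rule)
        pending.append((w, norm, target_cells))

    for i in range(0, len(pending), batch_size):
        chunk = pending[i:i + batch_size]
        inputs = np.stack([np.nan_to_num(s.coords, nan=0.0) for _, s, _ in chunk])
        masks = np.stack([s.missing for _, s, _ in chunk])
        pred = predict_batch(model, inputs, masks)
        for j, (w, norm, target_cells) in enumerate(chunk):
            mean_n = pred.mean[j]
            std_n = None if pred.std is None else pred.std[j]
            err = (float(std_n[norm.missing].mean())
                   if std_n is not None else None)
            if err is not None and err > error_threshold:
                reports.append(WindowReport(w, err, False, "error_above_threshold"))
                continue
            filled = norm.copy()
            filled.coords = np.where(norm.missing[..., None], mean_n,
                                     norm.coords)
            orig = inverse_transform(filled, norm.transform)
            weight = 1.0
            if std_n is not None:
                # inverse-variance weight from the window-mean variance
                weight = 1.0 / max(float((std_n[norm.missing] ** 2).mean()), 1e-12)
            acc[w:w + L][target_cells] += orig.coords[target_cells] * weight
            wsum[w:w + L][target_cells] += weight
            reports.append(WindowReport(w, err, True))

    filled_cells = wsum > 0
    coords_out[filled_cells] = acc[filled_cells] / wsum[filled_cells][:, None]
    still = recording.missing & ~filled_cells
    coords_out[still] = np.nan
    return ImputedRecording(coords_out, still, reports)
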