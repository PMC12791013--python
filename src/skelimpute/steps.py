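"""Step detection and swing-phase kinematics from ankle trajectories.

A locomotor step shows up as a peak in the smoothed ankle speed, flanked by
an acceleration burst (takeoff) and a deceleration valley (touchdown).  The
detector finds speed peaks passing height / prominence / width gates, then
anchors the swing start at the strongest acceleration before the peak and
the swing stop at the strongest deceleration after it (search bounded to
2 s and to the neighboring peaks).  Steps whose start-to-stop interval is
shorter than 0.6 s, or whose ankle is not lower at start and stop than
during the swing, are discarded.

The two duration rules act on different quantities: the 0.16-2 s range gates
the speed-peak width at half prominence, while the 0.6 s minimum applies to
the final start-to-stop interval.

Thresholds are expressed in the trajectory's native units per second (the
defaults assume mm for mouse-scale data) and are all parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import scipy.ndimage
import scipy.signal

from .errors import EmptyInputError
from .io import Recording


@dataclass
class StepGates:
    """Detection thresholds; units/s refer to the trajectory's native units."""

    min_height: float = 20.0
    min_prominence: float = 21.0
    peak_duration_s: tuple[float, float] = (0.16, 2.0)
    min_step_duration_s: float = 0.6
    height_check: bool = True
    valley_search_s: float = 2.0
    smooth_s: float = 0.1


@dataclass
class Step:
    """One detected swing phase."""

    side: str
    t_start: int
    t_peak: int
    t_stop: int
    stride_length: float = np.nan
    swing_duration: float = np.nan


def ankle_speed(traj: np.ndarray, fps: float,
                smooth_s: float = 0.1) -> np.ndarray:
    """Instantaneous speed (units/s) smoothed over ``smooth_s`` seconds.

    Per-frame Euclidean displacement times fps, then a moving average over
    round(smooth_s * fps) frames.  The input must be a contiguous segment
    without missing frames.
    """
    traj = np.asarray(traj, dtype=np.float64)
    if traj.ndim == 1:
        traj = traj[:, None]
    if np.isnan(traj).any():
        raise EmptyInputError("ankle_speed requires a gap-free segment")
    T = traj.shape[0]
    if T < 2:
        return np.zeros(T)
    speed = np.empty(T)
    speed[1:] = np.linalg.norm(np.diff(traj, axis=0), axis=1) * fps
    speed[0] = speed[1]
    w = max(int(round(smooth_s * fps)), 1)
    return scipy.ndimage.uniform_filter1d(speed, size=w)


def detect_steps(speed: np.ndarray, accel: np.ndarray, fps: float,
                 gates: StepGates | None = None,
                 height_series: np.ndarray | None = None,
                 side: str = "") -> list[Step]:
    """Find swing phases on aligned smoothed-speed / acceleration series.

    ``height_series`` (e.g. the ankle's vertical coordinate) enables the
    position check that start and stop lie lower than the swing.
    """
    g = gates or StepGates()
    speed = np.asarray(speed, dtype=np.float64)
    accel = np.asarray(accel, dtype=np.float64)
    if speed.shape != accel.shape:
        raise EmptyInputError("speed and accel must be aligned")
    T = speed.shape[0]
    wmin = g.peak_duration_s[0] * fps
    wmax = g.peak_duration_s[1] * fps
    peaks, _ = scipy.signal.find_peaks(
        speed, height=g.min_height, prominence=g.min_prominence,
        width=(wmin, wmax), rel_height=0.5)
    bound = int(round(g.valley_search_s * fps))
    smooth_w = max(int(round(g.smooth_s * fps)), 1)
    if len(peaks):
        # each peak's own extent (near-base width) bounds the takeoff and
        # touchdown search, so a neighboring bump cannot capture the anchor
        _, _, left_ips, right_ips = scipy.signal.peak_widths(
            speed, peaks, rel_height=0.97)
    steps: list[Step] = []
    for i, p in enumerate(peaks):
        lo = max(p - bound, 0, peaks[i - 1] if i > 0 else 0,
                 int(np.floor(left_ips[i])) - smooth_w)
        hi = min(p + bound, T - 1,
                 peaks[i + 1] if i + 1 < len(peaks) else T - 1,
                 int(np.ceil(right_ips[i])) + smooth_w)
        if lo >= p or p >= hi:
            continue  # no room to anchor takeoff/touchdown
        t_start = lo + int(np.argmax(accel[lo:p]))
        t_stop = p + 1 + int(np.argmin(accel[p + 1:hi + 1]))
        if (t_stop - t_start) / fps < g.min_step_duration_s:
            continue
        if g.height_check and height_series is not None:
            h = np.asarray(height_series, dtype=np.float64)
            interior = h[t_start + 1:t_stop]
            if interior.size == 0:
                continue
            swing_level = interior.mean()
            if not (h[t_start] < swing_level and h[t_stop] < swing_level):
                continue
        steps.append(Step(side, int(t_start), int(p), int(t_stop)))
    return steps


def step_features(step: Step, traj: np.ndarray, fps: float) -> Step:
    """Fill stride length (path length of the ankle over the swing) and
    swing duration (seconds) on a detected step."""
    traj = np.asarray(traj, dtype=np.float64)
    if traj.ndim == 1:
        traj = traj[:, None]
    seg = traj[step.t_start:step.t_stop + 1]
    if np.isnan(seg).any():
        raise EmptyInputError("stride length requires a gap-free swing")
    step.stride_length = float(
        np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())
    step.swing_duration = (step.t_stop - step.t_start) / fps
    return step


def contiguous_segments(missing: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of observed frames as half-open (start, stop)."""
    obs = ~np.asarray(missing, dtype=bool)
    padded = np.concatenate(([False], obs, [False])).astype(np.int8)
    d = np.diff(padded)
    return [(int(s), int(e)) for s, e in
            zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1))]


def detect_steps_in_trajectory(traj: np.ndarray, fps: float,
                               gates: StepGates | None = None,
                               missing: np.ndarray | None = None,
                               side: str = "") -> list[Step]:
    """Run detection on each contiguous non-missing segment of an ankle
    trajectory and return steps with features, indexed in original frames."""
    g = gates or StepGates()
    traj = np.asarray(traj, dtype=np.float64)
    if traj.ndim == 1:
        traj = traj[:, None]
    if missing is None:
        missing = np.isnan(traj).any(axis=1)
    steps: list[Step] = []
    min_len = max(int(round(g.min_step_duration_s * fps)) + 2, 4)
    for s0, s1 in contiguous_segments(missing):
        if s1 - s0 < min_len:
            continue
        seg = traj[s0:s1]
        speed = ankle_speed(seg, fps, g.smooth_s)
        accel = np.gradient(speed)
        height = seg[:, -1] if traj.shape[1] > 1 else seg[:, 0]
        for st in detect_steps(speed, accel, fps, g, height, side):
            st.t_start += s0
            st.t_peak += s0
            st.t_stop += s0
            steps.append(step_features(st, traj, fps))
    return steps


def count_steps_before_after(recording: Recording,
                             imputed,  # ImputedRecording
                             ankle_keypoints: list[str],
                             fps: float | None = None,
                             gates: StepGates | None = None
                             ) -> tuple[int, int, list[Step], list[Step]]:
    """Detect steps on the original and the imputed recording with the same
    detector configuration; windows rejected during imputation stay missing
    and keep splitting the segments."""
    fps = fps if fps is not None else recording.fps
    before: list[Step] = []
    after: list[Step] = []
    for name in ankle_keypoints:
        k = recording.keypoint_names.index(name)
        before.extend(detect_steps_in_trajectory(
            recording.coords[:, k], fps, gates, recording.missing[:, k], name))
        after.extend(detect_steps_in_trajectory(
            imputed.coords[:, k], fps, gates, imputed.still_missing[:, k], name))
    return len(before), len(after), before, after
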