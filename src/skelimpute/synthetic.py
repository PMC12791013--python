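"""Synthetic articulated-motion generator with known ground truth.

Emulates the statistical structure of animal pose recordings that the
imputation models rely on: a body drifting with a smoothly varying heading,
rigid keypoint offsets in the body frame, coherent sinusoidal limb
oscillations (all keypoints share one gait phase, so they are strongly
correlated), optional two-individual coupling, and additive Gaussian jitter.
Separate helpers inject realistic missingness patterns and build 1D
step-like ankle traces with construction-derived ground truth for the step
detector.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal

from .errors import ConfigError
from .io import Recording

MOUSE8_KEYPOINTS = ["left_hip", "right_hip", "left_knee", "right_knee",
                    "left_ankle", "right_ankle", "left_back", "right_back"]
FISH3_KEYPOINTS = ["head", "pectoral_fin", "tail"]

# body-frame offsets (units ~ mm), oscillation amplitude along the body axis,
# vertical lift amplitude and phase offset of the shared gait oscillator
_MOUSE8_BODY = {
    #                offset (x, y, z)      amp    lift  phase
    "left_hip":    ((-25.0,  12.0, 30.0),  2.0,  0.5,  0.0),
    "right_hip":   ((-25.0, -12.0, 30.0),  2.0,  0.5,  np.pi),
    "left_knee":   ((-32.0,  18.0, 18.0),  8.0,  2.0,  0.0),
    "right_knee":  ((-32.0, -18.0, 18.0),  8.0,  2.0,  np.pi),
    "left_ankle":  ((-38.0,  21.0,  6.0), 15.0,  5.0,  0.0),
    "right_ankle": ((-38.0, -21.0,  6.0), 15.0,  5.0,  np.pi),
    "left_back":   (( -5.0,   8.0, 36.0),  1.0,  0.5,  0.0),
    "right_back":  (( -5.0,  -8.0, 36.0),  1.0,  0.5,  np.pi),
}

_FISH3_BODY = {
    "head":         (( 12.0, 0.0, 0.0),  1.0, 0.5, 0.0),
    "pectoral_fin": ((  0.0, 3.0, 0.0),  4.0, 1.0, np.pi / 2),
    "tail":         ((-12.0, 0.0, 0.0),  8.0, 2.0, np.pi),
}


@dataclass
class MotionSpec:
    """Parameters of the articulated motion generator."""

    keypoint_names: list[str] = field(default_factory=lambda: list(MOUSE8_KEYPOINTS))
    body: dict = field(default_factory=lambda: dict(_MOUSE8_BODY))
    dims: int = 3
    gait_freq_hz: float = 2.0
    drift_speed: float = 40.0           # units / s
    heading_rate_std: float = 0.06      # rad / frame random walk
    n_individuals: int = 1
    interaction_strength: float = 0.0   # pull of individual 2 toward 1, 1/s
    noise_std: float = 0.5
    oscillation_scale: float = 1.0      # global multiplier on amplitudes

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ConfigError("dims must be 2 or 3")
        if self.n_individuals not in (1, 2):
            raise ConfigError("n_individuals must be 1 or 2")


def mouse8_spec(**overrides) -> MotionSpec:
    """Single mouse-like skeleton: hips, knees, ankles, back (K=8, 3D)."""
    return MotionSpec(**overrides)


def fish2x3_spec(interaction_strength: float = 1.0, **overrides) -> MotionSpec:
    """Two interacting fish-like skeletons (K=3 per animal, 3D)."""
    return MotionSpec(keypoint_names=list(FISH3_KEYPOINTS),
                      body=dict(_FISH3_BODY), n_individuals=2,
                      interaction_strength=interaction_strength,
                      drift_speed=60.0, gait_freq_hz=3.0, **overrides)


def _one_body(spec: MotionSpec, T: int, fps: float,
              rng: np.random.Generator, start: np.ndarray,
              attract_to: np.ndarray | None = None) -> np.ndarray:
    """Trajectory of one individual, (T, K, 3)."""
    K = len(spec.keypoint_names)
    theta = np.cumsum(rng.normal(0.0, spec.heading_rate_std, size=T))
    theta += rng.uniform(0, 2 * np.pi)
    center = np.zeros((T, 3))
    center[0, :2] = start[:2]
    step = spec.drift_speed / fps
    for t in range(1, T):
        v = np.array([np.cos(theta[t]), np.sin(theta[t]), 0.0]) * step
        if attract_to is not None and spec.interaction_strength > 0:
            v[:2] += (spec.interaction_strength / fps
                      * (attract_to[t - 1, :2] - center[t - 1, :2]) / fps)
        center[t] = center[t - 1] + v
    phase = (2 * np.pi * spec.gait_freq_hz * np.arange(T) / fps
             + rng.uniform(0, 2 * np.pi))
    coords = np.empty((T, K, 3))
    c, s = np.cos(theta), np.sin(theta)
    for k, name in enumerate(spec.keypoint_names):
        off, amp, lift, ph = spec.body[name]
        amp = amp * spec.oscillation_scale
        lift = lift * spec.oscillation_scale
        bx = off[0] + amp * np.sin(phase + ph)
        by = np.full(T, off[1])
        bz = off[2] + lift * np.sin(phase + ph + np.pi / 2)
        coords[:, k, 0] = center[:, 0] + c * bx - s * by
        coords[:, k, 1] = center[:, 1] + s * bx + c * by
        coords[:, k, 2] = center[:, 2] + bz
    return coords


def simulate_recording(spec: MotionSpec, T: int, fps: float = 60.0,
                       seed: int = 0, id: str = "synthetic") -> Recording:
    """Generate a complete recording; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    bodies = [_one_body(spec, T, fps, rng, rng.uniform(-50, 50, size=2))]
    if spec.n_individuals == 2:
        bodies.append(_one_body(spec, T, fps, rng,
                                rng.uniform(-50, 50, size=2),
                                attract_to=bodies[0].mean(axis=1)))
    coords = np.concatenate(bodies, axis=1)
    if spec.noise_std > 0:
        coords = coords + rng.normal(0.0, spec.noise_std, size=coords.shape)
    if spec.dims == 2:
        coords = coords[:, :, :2]
    names = list(spec.keypoint_names)
    individual_of = None
    if spec.n_individuals == 2:
        names = [f"{n}_1" for n in spec.keypoint_names] + \
                [f"{n}_2" for n in spec.keypoint_names]
        individual_of = np.repeat([0, 1], len(spec.keypoint_names))
    return Recording(id=id, fps=fps, keypoint_names=names, coords=coords,
                     individual_of=individual_of)


def linear_motion_recording(T: int, K: int = 8, D: int = 3, fps: float = 60.0,
                            seed: int = 0) -> Recording:
    """Exactly linear keypoint trajectories (zero noise).

    Linear interpolation recovers any interior gap on this recording
    perfectly, which bounds learned models from below.
    """
    rng = np.random.default_rng(seed)
    start = rng.uniform(-50, 50, size=(K, D))
    vel = rng.uniform(-1.0, 1.0, size=(K, D))
    t = np.arange(T)[:, None, None]
    coords = start[None] + vel[None] * t
    return Recording(id="linear", fps=fps,
                     keypoint_names=[f"kp{k}" for k in range(K)],
                     coords=coords)


def add_sample_noise(samples: list, levels: Sequence[float],
                     seed: int = 0) -> tuple[list, np.ndarray]:
    """Heteroscedastic fixture: add per-sample Gaussian jitter.

    Each (normalized) sample gets one noise level drawn from ``levels``
    applied to every coordinate; returns the noisy samples and the level
    assigned to each.  Predicted uncertainties of a well-calibrated model
    should track these levels.
    """
    rng = np.random.default_rng(seed)
    lv = np.asarray(list(levels), dtype=float)
    chosen = lv[rng.integers(0, len(lv), size=len(samples))]
    out = []
    for s, sigma in zip(samples, chosen):
        ns = s.copy()
        ns.coords = ns.coords + rng.normal(0.0, sigma, size=ns.coords.shape)
        out.append(ns)
    return out, chosen


# ---------------------------------------------------------------------------
# missingness injection


@dataclass
class MissingnessPattern:
    """Renewal-process missingness: per-frame probability that a gap event
    starts (per keypoint) and a gap-length distribution."""

    event_rate: float = 0.01
    length_pmf: dict[int, float] = field(
        default_factory=lambda: {n: 1.0 / 10 for n in range(1, 11)})
    keypoint_probs: np.ndarray | None = None  # relative rate per keypoint


def inject_missingness(recording: Recording, pattern: MissingnessPattern,
                       seed: int = 0) -> Recording:
    """Mark runs of frames missing, per keypoint, per the pattern.

    Gap events are separated by at least one observed frame (spacings drawn
    from a geometric law with the configured event rate), so run-length
    encoding the produced mask recovers exactly the injected events.
    """
    if pattern.event_rate <= 0:
        return Recording(recording.id, recording.fps,
                         list(recording.keypoint_names),
                         recording.coords.copy(), recording.missing.copy(),
                         recording.individual_of)
    rng = np.random.default_rng(seed)
    T, K, _ = recording.coords.shape
    lengths = np.array(sorted(pattern.length_pmf))
    probs = np.array([pattern.length_pmf[int(n)] for n in lengths])
    probs = probs / probs.sum()
    rel = (np.ones(K) if pattern.keypoint_probs is None
           else np.asarray(pattern.keypoint_probs, dtype=float))
    missing = recording.missing.copy()
    for k in range(K):
        rate = pattern.event_rate * rel[k] * K / rel.sum()
        if rate <= 0:
            continue
        t = int(rng.geometric(min(rate, 1.0)))
        while t < T - 1:
            n = int(rng.choice(lengths, p=probs))
            if t + n > T:
                break  # never truncate a gap: lengths stay exactly as drawn
            missing[t:t + n, k] = True
            t = t + n + int(rng.geometric(min(rate, 1.0)))  # >= 1 observed frame
    coords = recording.coords.copy()
    coords[missing] = np.nan
    return Recording(recording.id, recording.fps,
                     list(recording.keypoint_names), coords, missing,
                     recording.individual_of)


# ---------------------------------------------------------------------------
# step-trace fixture


@dataclass
class StepTruth:
    """Construction-derived ground truth for one speed bump."""

    t_start: int
    t_peak: int
    t_stop: int
    height: float
    duration_s: float
    valid: bool
    reason: str = ""


def make_step_trace(n_steps: int, fps: float = 60.0,
                    step_height: float = 30.0, step_duration: float = 0.8,
                    baseline_noise: float = 1.0, seed: int = 0,
                    heights: Sequence[float] | None = None,
                    durations: Sequence[float] | None = None,
                    gates: "dict | None" = None
                    ) -> tuple[np.ndarray, list[StepTruth]]:
    """Build an ankle-like trajectory with known step intervals.

    The speed profile is baseline noise plus tapered-cosine (Tukey) bumps of
    given height (units/s) and duration; the x position integrates the
    profile and a small vertical lift accompanies each bump so the
    start/stop-lower-than-swing position check holds.  Returns the (T, 3)
    trajectory and per-bump ground truth with start/peak/stop computed on the
    clean profile, and a validity flag evaluated against the detection gates.
    """
    from .steps import StepGates  # local import to avoid a cycle

    g = StepGates(**(gates or {}))
    hs = list(heights) if heights is not None else [step_height] * n_steps
    ds = list(durations) if durations is not None else [step_duration] * n_steps
    if len(hs) != n_steps or len(ds) != n_steps:
        raise ConfigError("heights/durations must have n_steps entries")
    rng = np.random.default_rng(seed)
    lead = int(round(1.5 * fps))
    bump_frames = [max(int(round(d * fps)), 4) for d in ds]
    T = lead + sum(bf + lead for bf in bump_frames)
    speed = np.zeros(T)
    lift = np.zeros(T)
    truths: list[StepTruth] = []
    pos = lead
    smooth_w = max(int(round(0.1 * fps)), 1)
    kernel = np.ones(smooth_w) / smooth_w
    for h, d, bf in zip(hs, ds, bump_frames):
        win = scipy.signal.windows.tukey(bf, alpha=0.3)
        speed[pos:pos + bf] += h * win
        # small vertical lift (proportional to the bump) for the
        # start/stop-lower-than-swing check; kept well below the horizontal
        # speed so it cannot push a sub-threshold bump over the height gate
        lift[pos:pos + bf] += (h / 30.0) * win
        # ground truth from the clean smoothed profile, same definitions as
        # the detector but computed on the noiseless bump in isolation
        clean = np.zeros(T)
        clean[pos:pos + bf] = h * win
        sm = np.convolve(clean, kernel, mode="same")
        accel = np.gradient(sm)
        lo = max(pos - smooth_w, 0)
        hi = min(pos + bf + smooth_w, T)
        t_peak = lo + int(np.argmax(sm[lo:hi]))
        t_start = lo + int(np.argmax(accel[lo:t_peak]))
        t_stop = t_peak + int(np.argmin(accel[t_peak:hi]))
        widths = scipy.signal.peak_widths(sm, [t_peak], rel_height=0.5)[0]
        width_s = float(widths[0]) / fps
        interval_s = (t_stop - t_start) / fps
        peak_h = float(sm[t_peak])
        valid, reason = True, ""
        if peak_h < g.min_height or peak_h < g.min_prominence:
            valid, reason = False, "height"
        elif not (g.peak_duration_s[0] <= width_s <= g.peak_duration_s[1]):
            valid, reason = False, "width"
        elif interval_s < g.min_step_duration_s:
            valid, reason = False, "interval"
        truths.append(StepTruth(t_start, t_peak, t_stop, peak_h, d,
                                valid, reason))
        pos += bf + lead
    if baseline_noise > 0:
        speed = speed + rng.normal(0.0, baseline_noise, size=T)
    x = np.cumsum(speed) / fps
    traj = np.stack([x, np.zeros(T), lift], axis=1)
    return traj, truths
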