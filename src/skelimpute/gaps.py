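"""Empirical missingness model and artificial gap / switch augmentation.

Real tracking data lose keypoints in characteristic ways: some keypoints drop
out more often than others, and gap lengths follow dataset-specific
distributions.  Three empirical distributions summarize this process:

* ``p_keypoint`` — probability that a missing event hits keypoint k,
* ``gap_length_pmf[k]`` — distribution of gap lengths given keypoint k,
* ``intergap_pmf`` — distribution of spacings between consecutive gaps.

Training gaps are drawn from these distributions and applied to complete
samples: masked cells are zero-filled in the model input and flagged in a
binary mask, while the untouched coordinates remain the reconstruction
target.  Gap lengths are capped to [1, L-2] so the first and last frame of
the masked keypoint stay observed, which keeps the linear-interpolation
baseline applicable to every artificial gap.

The switch augmentation exchanges two keypoints' input coordinates over a
random sub-interval while leaving the target untouched, teaching the model to
recover from tracking identity swaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, EmptyInputError, ShapeError
from .io import Recording, Sample

DEFAULT_MAX_GAP = 58  # L - 2 for the standard 60-frame sample


@dataclass
class GapStats:
    """Empirical missingness model estimated from recordings."""

    p_keypoint: np.ndarray                   # (K,), sums to 1
    gap_length_pmf: list[dict[int, float]]   # per keypoint: {length: prob}
    intergap_pmf: dict[int, float]           # {spacing: prob}
    source_frame_count: int = 0

    def __post_init__(self) -> None:
        self.p_keypoint = np.asarray(self.p_keypoint, dtype=np.float64)
        s = self.p_keypoint.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ConfigError(f"p_keypoint must sum to 1, got {s}")
        for k, pmf in enumerate(self.gap_length_pmf):
            if pmf and not np.isclose(sum(pmf.values()), 1.0, atol=1e-9):
                raise ConfigError(f"gap_length_pmf[{k}] must sum to 1")
        if self.intergap_pmf and not np.isclose(sum(self.intergap_pmf.values()),
                                                1.0, atol=1e-9):
            raise ConfigError("intergap_pmf must sum to 1")

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {"p_keypoint": self.p_keypoint.tolist(),
               "gap_length_pmf": [{str(k): v for k, v in pmf.items()}
                                  for pmf in self.gap_length_pmf],
               "intergap_pmf": {str(k): v for k, v in self.intergap_pmf.items()},
               "source_frame_count": self.source_frame_count}
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "GapStats":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        obj = json.loads(text)
        return cls(np.asarray(obj["p_keypoint"]),
                   [{int(k): v for k, v in pmf.items()}
                    for pmf in obj["gap_length_pmf"]],
                   {int(k): v for k, v in obj["intergap_pmf"].items()},
                   obj.get("source_frame_count", 0))

    @classmethod
    def uniform(cls, n_keypoints: int, max_length: int = DEFAULT_MAX_GAP,
                exclude_keypoints: list[int] | None = None) -> "GapStats":
        """Uniform fallback used when no native missingness is observed."""
        excl = set(exclude_keypoints or ())
        p = np.array([0.0 if k in excl else 1.0 for k in range(n_keypoints)])
        if p.sum() == 0:
            raise ConfigError("all keypoints excluded from gap sampling")
        p /= p.sum()
        u = {n: 1.0 / max_length for n in range(1, max_length + 1)}
        return cls(p, [dict(u) for _ in range(n_keypoints)], dict(u), 0)


@dataclass
class GapSpec:
    """One artificial gap: keypoint, start frame within sample, length."""

    keypoint: int
    start: int
    length: int


@dataclass
class MaskedSample:
    """Training/inference unit: zero-filled input, gap mask, ground truth."""

    input: np.ndarray      # (L, K, D), zeros at gap cells
    gap_mask: np.ndarray   # (L, K) bool, True = artificially masked
    target: np.ndarray     # (L, K, D) ground truth
    switch_record: list[tuple[int, int, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# estimation


def missing_runs(mask_column: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1D boolean array as (start, length)."""
    m = np.asarray(mask_column, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def estimate_gap_stats(recordings: list[Recording],
                       exclude_keypoints: list[int] | None = None,
                       uniform_max_length: int = DEFAULT_MAX_GAP) -> GapStats:
    """Estimate the empirical missingness model from recordings.

    Gap events are maximal runs of consecutive missing frames per keypoint.
    ``p_keypoint`` is proportional to the event count on each keypoint; the
    length pmf comes from event lengths and the inter-gap pmf from spacings
    between consecutive events on the same keypoint within one recording.
    With no observed missingness, all distributions fall back to uniform
    (lengths and spacings over [1, uniform_max_length]).  ``exclude_keypoints``
    forces those keypoints' sampling probability to 0 (e.g. near-rigid
    keypoints that never need imputation).
    """
    if not recordings:
        raise EmptyInputError("need at least one recording")
    K = recordings[0].n_keypoints
    excl = set(exclude_keypoints or ())
    counts = np.zeros(K)
    lengths: list[list[int]] = [[] for _ in range(K)]
    spacings: list[int] = []
    total_frames = 0
    for rec in recordings:
        if rec.n_keypoints != K:
            raise ShapeError("recordings disagree on keypoint count")
        total_frames += rec.n_frames
        for k in range(K):
            runs = missing_runs(rec.missing[:, k])
            counts[k] += len(runs)
            lengths[k].extend(ln for _, ln in runs)
            for (s0, l0), (s1, _) in zip(runs, runs[1:]):
                spacings.append(s1 - (s0 + l0))
    uniform = {n: 1.0 / uniform_max_length
               for n in range(1, uniform_max_length + 1)}
    if counts.sum() == 0:
        stats = GapStats.uniform(K, uniform_max_length,
                                 sorted(excl) if excl else None)
        stats.source_frame_count = total_frames
        return stats
    p = counts.copy()
    p[list(excl)] = 0.0
    if p.sum() == 0:
        p = np.array([0.0 if k in excl else 1.0 for k in range(K)])
    p /= p.sum()
    length_pmf = []
    for k in range(K):
        if lengths[k]:
            vals, cnt = np.unique(lengths[k], return_counts=True)
            length_pmf.append({int(v): c / cnt.sum() for v, c in zip(vals, cnt)})
        else:
            length_pmf.append(dict(uniform))
    if spacings:
        vals, cnt = np.unique(spacings, return_counts=True)
        pos = vals > 0
        vals, cnt = vals[pos], cnt[pos]
    if spacings and cnt.sum() > 0:
        intergap = {int(v): c / cnt.sum() for v, c in zip(vals, cnt)}
    else:
        intergap = dict(uniform)
    return GapStats(p, length_pmf, intergap, total_frames)


# ---------------------------------------------------------------------------
# sampling


def _truncated_choice(pmf: dict[int, float], lo: int, hi: int,
                      rng: np.random.Generator) -> int:
    """Draw from pmf truncated to [lo, hi] and renormalized; uniform fallback."""
    keys = np.array([k for k in pmf if lo <= k <= hi], dtype=np.int64)
    if keys.size == 0:
        return int(rng.integers(lo, hi + 1))
    probs = np.array([pmf[int(k)] for k in keys])
    total = probs.sum()
    if total <= 0:
        return int(rng.integers(lo, hi + 1))
    return int(rng.choice(keys, p=probs / total))


def sample_gaps(stats: GapStats,
                n_keypoints_missing: int,
                L: int,
                rng: np.random.Generator) -> list[GapSpec]:
    """Draw artificial gaps mimicking the empirical missingness process.

    Keypoints are drawn without replacement proportionally to ``p_keypoint``;
    each gap length from the keypoint's length pmf truncated to [1, L-2];
    the start offset from the inter-gap pmf truncated to the valid start
    range [1, L-1-length] (uniform fallback when degenerate), so the first
    and last frame of the masked keypoint always stay observed.
    """
    if L < 3:
        raise ConfigError(f"sample length must be >= 3 to place a gap, got {L}")
    K = stats.p_keypoint.shape[0]
    n = int(n_keypoints_missing)
    eligible = int((stats.p_keypoint > 0).sum())
    if n < 1 or n > min(K, eligible):
        raise ConfigError(
            f"n_keypoints_missing={n} outside [1, {min(K, eligible)}]")
    p = stats.p_keypoint.copy()
    specs: list[GapSpec] = []
    for _ in range(n):
        p_norm = p / p.sum()
        k = int(rng.choice(K, p=p_norm))
        p[k] = 0.0
        length = _truncated_choice(stats.gap_length_pmf[k], 1, L - 2, rng)
        start = _truncated_choice(stats.intergap_pmf, 1, L - 1 - length, rng)
        specs.append(GapSpec(k, start, length))
    return specs


def apply_gaps(sample: Sample, gaps: list[GapSpec],
               allow_incomplete: bool = False) -> MaskedSample:
    """Zero-fill gap cells; keep ground truth as the target.

    Overlapping specs on one keypoint merge through the boolean mask.  In
    training mode the sample must be complete (no native missing values).
    """
    if not allow_incomplete and not sample.is_complete:
        raise ConfigError("training samples must be complete; "
                          "pass allow_incomplete=True for inference use")
    L, K, _ = sample.coords.shape
    gap_mask = np.zeros((L, K), dtype=bool)
    for g in gaps:
        if not (1 <= g.length <= L - 2 and 1 <= g.start
                and g.start + g.length <= L - 1):
            raise ConfigError(f"gap spec {g} violates [1, L-2] placement")
        gap_mask[g.start:g.start + g.length, g.keypoint] = True
    target = sample.coords.copy()
    inp = sample.coords.copy()
    inp[gap_mask] = 0.0
    inp[sample.missing] = 0.0  # native missing also zero-filled for the model
    return MaskedSample(inp, gap_mask, target)


def apply_switch(masked: MaskedSample, prob: float,
                 rng: np.random.Generator,
                 force: tuple[int, int, int, int] | None = None) -> MaskedSample:
    """With probability ``prob`` exchange two keypoints' input coordinates
    over a random sub-interval.  The target is never modified: the loss is
    computed against the unswitched ground truth.  ``force=(a, b, t0, t1)``
    bypasses the draw (testing hook)."""
    if not 0.0 <= prob <= 1.0:
        raise ConfigError(f"switch probability must be in [0, 1], got {prob}")
    L, K, _ = masked.input.shape
    out = MaskedSample(masked.input.copy(), masked.gap_mask.copy(),
                       masked.target, list(masked.switch_record))
    if K < 2:
        return out
    if force is None:
        if rng.random() >= prob:
            return out
        a, b = rng.choice(K, size=2, replace=False)
        t0 = int(rng.integers(0, L - 1))
        t1 = int(rng.integers(t0 + 1, L + 1))
    else:
        a, b, t0, t1 = force
    a, b = int(a), int(b)
    out.input[t0:t1, [a, b]] = out.input[t0:t1, [b, a]]
    out.switch_record.append((a, b, t0, t1))
    return out
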