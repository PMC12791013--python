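"""Missingness estimation and artificial gap / switch sampling."""

import numpy as np
import pytest

from skelimpute import gaps as G
from skelimpute.errors import ConfigError
from skelimpute.io import Recording, Sample


def _recording_from_mask(mask, rng):
    T, K = mask.shape
    coords = rng.normal(size=(T, K, 2))
    coords[mask] = np.nan
    return Recording("m", 60.0, [f"k{i}" for i in range(K)], coords, mask)


def _rle_oracle(column):
    """Independent run-length encoder: explicit scan."""
    runs, start = [], None
    for i, v in enumerate(column):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(column) - start))
    return runs


class TestEstimateGapStats:
    def test_single_keypoint_constant_runs(self, rng):
        mask = np.zeros((200, 4), bool)
        for s in (10, 50, 90):
            mask[s:s + 5, 2] = True
        stats = G.estimate_gap_stats([_recording_from_mask(mask, rng)])
        assert np.allclose(stats.p_keypoint, [0, 0, 1, 0])
        assert stats.gap_length_pmf[2] == {5: 1.0}

    def test_no_missing_falls_back_to_uniform(self, rng):
        mask = np.zeros((100, 3), bool)
        stats = G.estimate_gap_stats([_recording_from_mask(mask, rng)],
                                     uniform_max_length=58)
        assert np.allclose(stats.p_keypoint, 1 / 3)
        assert len(stats.gap_length_pmf[0]) == 58
        assert np.isclose(sum(stats.gap_length_pmf[0].values()), 1.0)

    def test_agrees_with_rle_oracle_on_random_masks(self, rng):
        mask = rng.random((500, 5)) < 0.08
        stats = G.estimate_gap_stats([_recording_from_mask(mask, rng)])
        for k in range(5):
            runs = _rle_oracle(mask[:, k])
            if not runs:
                continue
            lengths, counts = np.unique([l for _, l in runs],
                                        return_counts=True)
            expected = {int(l): c / counts.sum()
                        for l, c in zip(lengths, counts)}
            assert stats.gap_length_pmf[k] == pytest.approx(expected)
        total_runs = sum(len(_rle_oracle(mask[:, k])) for k in range(5))
        counts_est = stats.p_keypoint * total_runs
        assert np.allclose(sorted(counts_est),
                           sorted(len(_rle_oracle(mask[:, k]))
                                  for k in range(5)))

    def test_excluded_keypoints_get_zero_probability(self, rng):
        mask = rng.random((300, 4)) < 0.1
        stats = G.estimate_gap_stats([_recording_from_mask(mask, rng)],
                                     exclude_keypoints=[0, 3])
        assert stats.p_keypoint[0] == 0 and stats.p_keypoint[3] == 0
        assert np.isclose(stats.p_keypoint.sum(), 1.0)

    def test_json_round_trip(self, rng):
        mask = rng.random((300, 3)) < 0.1
        stats = G.estimate_gap_stats([_recording_from_mask(mask, rng)])
        back = G.GapStats.from_json(stats.to_json())
        assert np.allclose(back.p_keypoint, stats.p_keypoint)
        assert back.gap_length_pmf == stats.gap_length_pmf
        assert back.intergap_pmf == stats.intergap_pmf


class TestSampleGaps:
    def test_lengths_capped_to_valid_interval(self, rng):
        stats = G.GapStats.uniform(4, max_length=200)
        for _ in range(300):
            (g,) = G.sample_gaps(stats, 1, 60, rng)
            assert 1 <= g.length <= 58
            assert g.start >= 1 and g.start + g.length <= 59

    def test_one_hot_keypoint_distribution(self, rng):
        stats = G.GapStats(np.array([0.0, 1.0, 0.0]),
                           [{3: 1.0}] * 3, {5: 1.0})
        for _ in range(50):
            (g,) = G.sample_gaps(stats, 1, 60, rng)
            assert g.keypoint == 1 and g.length == 3

    def test_keypoint_frequencies_follow_p(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        stats = G.GapStats(p, [{2: 1.0}] * 3, {5: 1.0})
        draws = np.array([G.sample_gaps(stats, 1, 60, rng)[0].keypoint
                          for _ in range(10_000)])
        freq = np.bincount(draws, minlength=3) / 10_000
        assert np.abs(freq - p).max() < 0.02

    def test_without_replacement_distinct_keypoints(self, rng):
        stats = G.GapStats.uniform(5, 58)
        for _ in range(50):
            specs = G.sample_gaps(stats, 3, 60, rng)
            assert len({g.keypoint for g in specs}) == 3

    def test_short_sample_raises(self, rng):
        with pytest.raises(ConfigError):
            G.sample_gaps(G.GapStats.uniform(3), 1, 2, rng)


class TestApplyGaps:
    def _sample(self, rng, L=60, K=4):
        return Sample("s", 0, rng.normal(size=(L, K, 3)),
                      np.zeros((L, K), bool))

    def test_empty_gap_list_is_identity(self, rng):
        s = self._sample(rng)
        m = G.apply_gaps(s, [])
        assert np.array_equal(m.input, m.target)
        assert not m.gap_mask.any()

    def test_gap_zeroes_exactly_its_cells(self, rng):
        s = self._sample(rng)
        m = G.apply_gaps(s, [G.GapSpec(1, 10, 5)])
        assert (m.input[10:15, 1] == 0).all()
        assert m.gap_mask.sum() == 5
        assert (m.input[m.gap_mask] == 0).all()
        off = ~m.gap_mask
        assert np.array_equal(m.input[off], m.target[off])

    def test_overlapping_specs_merge(self, rng):
        s = self._sample(rng)
        m = G.apply_gaps(s, [G.GapSpec(1, 10, 5), G.GapSpec(1, 12, 6),
                             G.GapSpec(2, 3, 4)])
        # merged: keypoint 1 covers [10, 18), keypoint 2 covers [3, 7)
        assert m.gap_mask.sum() == 8 + 4

    def test_unmask_recovers_sample(self, rng):
        s = self._sample(rng)
        m = G.apply_gaps(s, [G.GapSpec(0, 5, 20)])
        restored = m.input.copy()
        restored[m.gap_mask] = m.target[m.gap_mask]
        assert np.array_equal(restored, s.coords)

    def test_incomplete_sample_rejected_in_training_mode(self, rng):
        s = self._sample(rng)
        s.missing[0, 0] = True
        with pytest.raises(ConfigError):
            G.apply_gaps(s, [G.GapSpec(1, 10, 5)])


class TestApplySwitch:
    def _masked(self, rng):
        s = Sample("s", 0, rng.normal(size=(60, 4, 3)),
                   np.zeros((60, 4), bool))
        return G.apply_gaps(s, [G.GapSpec(0, 10, 10)])

    def test_probability_zero_is_identity(self, rng):
        m = self._masked(rng)
        out = G.apply_switch(m, 0.0, rng)
        assert np.array_equal(out.input, m.input)
        assert out.switch_record == []

    def test_forced_switch_exchanges_interval_only(self, rng):
        m = self._masked(rng)
        out = G.apply_switch(m, 1.0, rng, force=(0, 1, 5, 15))
        assert np.array_equal(out.input[5:15, 0], m.input[5:15, 1])
        assert np.array_equal(out.input[5:15, 1], m.input[5:15, 0])
        assert np.array_equal(out.input[:5], m.input[:5])
        assert np.array_equal(out.input[15:], m.input[15:])
        assert np.array_equal(out.target, m.target)  # loss target untouched
        assert out.switch_record == [(0, 1, 5, 15)]

    def test_single_keypoint_is_noop(self, rng):
        coords = rng.normal(size=(60, 2, 3))
        # K=2 is the minimum; check K<2 path via a crafted MaskedSample
        m = G.MaskedSample(coords[:, :1], np.zeros((60, 1), bool),
                           coords[:, :1].copy())
        out = G.apply_switch(m, 1.0, rng)
        assert np.array_equal(out.input, m.input)
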