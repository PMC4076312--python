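import numpy as np
import pytest

from lateralize.bootstrap_li import (
    BootstrapConfig,
    TMapVolume,
    compute_hfli,
    compute_hfli_ladder,
    extract_supra,
    li_value,
    load_volume,
    save_volume,
)
from lateralize.synthetic import generate_tmap


def brute_force_hfli(volume, config):
    """Independent re-implementation of the trimmed-bootstrap index.

    Follows the same resampling schedule (sorted voxel values, one spawned
    child generator per hemisphere, row-wise index draws) but builds the
    pairwise combination set with explicit Python loops.
    """
    left, right = extract_supra(volume, config.threshold)

    def clamp(n):
        return int(min(max(round(config.k * n), config.min_sample),
                       config.max_sample))

    ss = np.random.SeedSequence(config.seed)
    rng_l, rng_r = [np.random.default_rng(s) for s in ss.spawn(2)]
    sums_l = [
        sum(left[j] for j in rng_l.integers(0, left.size, size=clamp(left.size)))
        for _ in range(config.n_iter)
    ]
    sums_r = [
        sum(right[j] for j in rng_r.integers(0, right.size, size=clamp(right.size)))
        for _ in range(config.n_iter)
    ]
    pairs = sorted(
        100.0 * (sl - sr) / (sl + sr) for sl in sums_l for sr in sums_r
    )
    t = int(np.floor(config.trim_fraction * len(pairs)))
    kept = pairs[t : len(pairs) - t]
    return sum(kept) / len(kept)


class TestExtraction:
    def test_all_negative_volume_yields_empty(self):
        vol = TMapVolume(
            np.full((4, 2, 2), -1.0),
            np.r_[np.ones(2, bool), np.zeros(2, bool)][:, None, None]
            * np.ones((4, 2, 2), bool),
            np.r_[np.zeros(2, bool), np.ones(2, bool)][:, None, None]
            * np.ones((4, 2, 2), bool),
        )
        left, right = extract_supra(vol, 0.0)
        assert left.size == 0 and right.size == 0

    @pytest.mark.parametrize(
        "threshold, expect_left, expect_right",
        [(0.0, [1, 2], [3]), (2.5, [], [3])],
    )
    def test_thresholding_is_strict(self, threshold, expect_left, expect_right):
        values = np.zeros((2, 3, 1))
        left = np.zeros((2, 3, 1), bool)
        right = np.zeros((2, 3, 1), bool)
        left[0] = True
        right[1] = True
        values[0, :, 0] = [1, 2, 0]
        values[1, :, 0] = [3, 0, -1]
        vol = TMapVolume(values, left, right)
        l, r = extract_supra(vol, threshold)
        assert l.tolist() == expect_left and r.tolist() == expect_right

    def test_exclusion_mask_removed_first(self):
        values = np.ones((2, 2, 1))
        left = np.zeros((2, 2, 1), bool); left[0] = True
        right = np.zeros((2, 2, 1), bool); right[1] = True
        excl = np.zeros((2, 2, 1), bool); excl[:, 0] = True
        vol = TMapVolume(values, left, right, excl)
        l, r = extract_supra(vol, 0.0)
        assert l.size == 1 and r.size == 1


class TestLiValue:
    @pytest.mark.parametrize(
        "l, r, expected", [(10, 0, 100.0), (5, 5, 0.0), (3, 1, 50.0)]
    )
    def test_arithmetic(self, l, r, expected):
        assert li_value(l, r) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            li_value(0.0, 0.0)


class TestComputeHfli:
    def test_mirror_symmetric_volume_is_exactly_zero(self):
        vol = generate_tmap((8, 8, 8), effect_left=2.0, effect_right=2.0,
                            noise_sd=0.0, seed=0)
        res = compute_hfli(vol, BootstrapConfig(seed=5))
        assert res.valid and res.hfli == 0.0

    def test_left_only_activation_is_plus_100(self):
        vol = generate_tmap((8, 8, 8), effect_left=5.0, effect_right=-1.0,
                            noise_sd=0.0, seed=0)
        res = compute_hfli(vol, BootstrapConfig(seed=5))
        assert res.valid and res.hfli == 100.0

    def test_matches_brute_force_oracle(self, twenty_voxel_volume):
        config = BootstrapConfig(seed=99, n_iter=40)
        res = compute_hfli(twenty_voxel_volume, config)
        oracle = brute_force_hfli(twenty_voxel_volume, config)
        assert res.valid
        assert res.hfli == pytest.approx(oracle, abs=1e-12)

    def test_deterministic_antisymmetry(self, flat_volume):
        config = BootstrapConfig(seed=3)
        res = compute_hfli(flat_volume, config)
        swapped = compute_hfli(flat_volume.swapped(), config)
        # constant per hemisphere: every pairwise combination is +-100/3
        assert res.hfli == pytest.approx(100.0 / 3)
        assert swapped.hfli == pytest.approx(-res.hfli)

    def test_stochastic_antisymmetry_with_mirrored_seed(self, twenty_voxel_volume):
        """Swapping hemispheres and the per-hemisphere generators together
        negates the index exactly; the resample sizes here are equal so the
        same draws apply to the same voxel values."""
        config = BootstrapConfig(seed=21)
        mirrored = BootstrapConfig(seed=21, mirror_seed=True)
        res = compute_hfli(twenty_voxel_volume, config)
        swapped = compute_hfli(twenty_voxel_volume.swapped(), mirrored)
        assert swapped.hfli == pytest.approx(-res.hfli, abs=1e-12)

    def test_scale_invariance(self, twenty_voxel_volume):
        config = BootstrapConfig(seed=8)
        res = compute_hfli(twenty_voxel_volume, config)
        scaled = TMapVolume(
            twenty_voxel_volume.values * 7.5,
            twenty_voxel_volume.left_mask,
            twenty_voxel_volume.right_mask,
            twenty_voxel_volume.exclusion_mask,
        )
        res2 = compute_hfli(scaled, config)
        assert res2.hfli == pytest.approx(res.hfli, abs=1e-9)

    def test_voxel_order_invariance(self, twenty_voxel_volume, rng):
        """Shuffling voxel storage within hemispheres leaves the index alone."""
        config = BootstrapConfig(seed=13)
        res = compute_hfli(twenty_voxel_volume, config)
        v = twenty_voxel_volume
        values = v.values.copy()
        for mask in (v.left_mask, v.right_mask):
            vals = values[mask]
            values[mask] = rng.permutation(vals)
        res2 = compute_hfli(TMapVolume(values, v.left_mask, v.right_mask), config)
        assert res2.hfli == res.hfli

    def test_too_few_voxels_flagged_invalid(self):
        values = np.zeros((4, 1, 1))
        left = np.zeros((4, 1, 1), bool); left[:2] = True
        right = np.zeros((4, 1, 1), bool); right[2:] = True
        values[left] = [3.0, 2.0]
        values[right] = [1.0, 4.0]
        res = compute_hfli(TMapVolume(values, left, right), BootstrapConfig())
        assert not res.valid and "fewer than" in res.reason

    def test_count_mode(self, twenty_voxel_volume):
        res = compute_hfli(
            twenty_voxel_volume, BootstrapConfig(weighting="count", seed=0)
        )
        assert res.hfli == pytest.approx(
            li_value(res.n_left_voxels, res.n_right_voxels)
        )

    def test_threshold_ladder_runs(self, twenty_voxel_volume):
        res = compute_hfli_ladder(
            twenty_voxel_volume, thresholds=[0.0, 0.5, 1.0],
            config=BootstrapConfig(seed=4),
        )
        assert res.valid and -100 <= res.hfli <= 100


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 0.0},
            {"k": 1.5},
            {"min_sample": 10, "max_sample": 5},
            {"trim_fraction": 0.5},
            {"weighting": "median"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BootstrapConfig(**kwargs)


class TestNiftiRoundTrip:
    def test_save_and_load(self, tmp_path, twenty_voxel_volume):
        save_volume(twenty_voxel_volume, tmp_path, stem="fix")
        vol = load_volume(
            tmp_path / "fix.nii",
            tmp_path / "fix_left.nii",
            tmp_path / "fix_right.nii",
            tmp_path / "fix_exclude.nii",
        )
        assert np.allclose(vol.values, twenty_voxel_volume.values)
        assert np.array_equal(vol.left_mask, twenty_voxel_volume.left_mask)
        res_a = compute_hfli(vol, BootstrapConfig(seed=1))
        res_b = compute_hfli(twenty_voxel_volume, BootstrapConfig(seed=1))
        assert res_a.hfli == res_b.hfli
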