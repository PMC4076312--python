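"""Bootstrap hemispheric functional laterality index (HFLI) from t-maps.

Given a voxelwise t-statistic volume from a language contrast plus left/right
hemisphere masks, the index contrasts summed suprathreshold activation between
hemispheres on a -100 (purely right) to +100 (purely left) scale.  Rather than
a single ratio, the index is a trimmed mean over all pairwise combinations of
per-hemisphere bootstrap resamples, which makes it robust to a handful of
extreme voxels.

Procedure for each hemisphere: take the suprathreshold voxel values, draw
``n_iter`` resamples with replacement of size ``clamp(round(k * n_voxels),
min_sample, max_sample)``, and record the sum of each resample.  All
``n_iter x n_iter`` left/right sum pairs are turned into indices
``100 * (L - R) / (L + R)``; the lowest and highest ``trim_fraction`` of the
combinations are discarded and the mean of the rest is the HFLI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TMapVolume",
    "BootstrapConfig",
    "LateralityIndex",
    "extract_supra",
    "li_value",
    "compute_hfli",
    "compute_hfli_ladder",
    "load_volume",
    "save_volume",
]


@dataclass
class TMapVolume:
    """A 3-D t-statistic grid with hemisphere and exclusion masks."""

    values: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.left_mask = np.asarray(self.left_mask, dtype=bool)
        self.right_mask = np.asarray(self.right_mask, dtype=bool)
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
        shapes = {
            self.values.shape,
            self.left_mask.shape,
            self.right_mask.shape,
            self.exclusion_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"volume and masks must share one shape, got {shapes}")
        if np.any(self.left_mask & self.right_mask & ~self.exclusion_mask):
            raise ValueError("left and right masks overlap outside the exclusion mask")

    def swapped(self) -> "TMapVolume":
        """Same volume with the hemisphere masks exchanged."""
        return TMapVolume(
            self.values, self.right_mask, self.left_mask, self.exclusion_mask
        )


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling schedule for the bootstrap index.

    Defaults: positive t-map threshold (0), resample ratio k = 0.25 with
    sample sizes clamped to [5, 1000] voxels, 100 resamples per hemisphere and
    25% trimming per tail of the pairwise combination distribution.
    """

    threshold: float = 0.0
    k: float = 0.25
    min_sample: int = 5
    max_sample: int = 1000
    n_iter: int = 100
    trim_fraction: float = 0.25
    seed: int = 0
    weighting: str = "sum"  # "sum" (magnitude-weighted) or "count"
    # swap the per-hemisphere child generators; with the hemisphere masks
    # also swapped this makes the index negate exactly
    mirror_seed: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.k <= 1):
            raise ValueError("resample ratio k must be in (0, 1]")
        if self.min_sample > self.max_sample:
            raise ValueError("min_sample must not exceed max_sample")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.weighting not in ("sum", "count"):
            raise ValueError("weighting must be 'sum' or 'count'")


@dataclass
class LateralityIndex:
    hfli: float
    n_left_voxels: int
    n_right_voxels: int
    valid: bool
    reason: str = ""


def extract_supra(
    volume: TMapVolume, threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Suprathreshold voxel values per hemisphere, sorted ascending.

    The exclusion mask is removed before thresholding; the comparison is
    strictly greater-than, so a zero threshold keeps the positive t-map only.
    Sorting makes downstream seeded resampling invariant to the storage order
    of voxels.
    """
    excl = volume.exclusion_mask
    left = volume.values[volume.left_mask & ~excl]
    right = volume.values[volume.right_mask & ~excl]
    return np.sort(left[left > threshold]), np.sort(right[right > threshold])


def li_value(sum_left: float, sum_right: float) -> float:
    """Laterality index 100 * (L - R) / (L + R); undefined when both are 0."""
    total = sum_left + sum_right
    if total == 0:
        raise ValueError("laterality index undefined when both sums are zero")
    return 100.0 * (sum_left - sum_right) / total


def _resample_sums(
    values: np.ndarray, size: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(n_iter, size))
    return values[idx].sum(axis=1)


def compute_hfli(volume: TMapVolume, config: BootstrapConfig | None = None) -> LateralityIndex:
    """Trimmed-bootstrap laterality index of a t-map volume.

    Returns an invalid result (with a reason) when a hemisphere has fewer
    suprathreshold voxels than ``min_sample`` but is not empty; a completely
    silent hemisphere against an adequately activated one gives +/-100.
    """
    config = config or BootstrapConfig()
    left, right = extract_supra(volume, config.threshold)
    n_left, n_right = left.size, right.size

    if n_left == 0 and n_right == 0:
        return LateralityIndex(np.nan, 0, 0, False, "no suprathreshold voxels")
    if n_left == 0:
        if n_right >= config.min_sample:
            return LateralityIndex(-100.0, 0, n_right, True)
        return LateralityIndex(np.nan, 0, n_right, False, "too few voxels")
    if n_right == 0:
        if n_left >= config.min_sample:
            return LateralityIndex(100.0, n_left, 0, True)
        return LateralityIndex(np.nan, n_left, 0, False, "too few voxels")
    if n_left < config.min_sample or n_right < config.min_sample:
        return LateralityIndex(
            np.nan,
            n_left,
            n_right,
            False,
            f"fewer than {config.min_sample} suprathreshold voxels in a hemisphere",
        )

    if config.weighting == "count":
        return LateralityIndex(li_value(n_left, n_right), n_left, n_right, True)

    def clamp(n: int) -> int:
        return int(np.clip(round(config.k * n), config.min_sample, config.max_sample))

    children = np.random.SeedSequence(config.seed).spawn(2)
    if config.mirror_seed:
        children = children[::-1]
    rng_left, rng_right = [np.random.default_rng(s) for s in children]
    sums_left = _resample_sums(left, clamp(n_left), config.n_iter, rng_left)
    sums_right = _resample_sums(right, clamp(n_right), config.n_iter, rng_right)

    with np.errstate(divide="ignore", invalid="ignore"):
        pairs = (
            100.0
            * (sums_left[:, None] - sums_right[None, :])
            / (sums_left[:, None] + sums_right[None, :])
        ).ravel()
    pairs = pairs[np.isfinite(pairs)]
    if pairs.size == 0:
        return LateralityIndex(
            np.nan, n_left, n_right, False, "all pairwise indices undefined"
        )
    pairs.sort()
    n_trim = int(np.floor(config.trim_fraction * pairs.size))
    kept = pairs[n_trim : pairs.size - n_trim]
    return LateralityIndex(float(kept.mean()), n_left, n_right, True)


def compute_hfli_ladder(
    volume: TMapVolume,
    thresholds,
    config: BootstrapConfig | None = None,
) -> LateralityIndex:
    """Multi-threshold variant: threshold-weighted average of per-threshold
    indices (weights proportional to 1-based threshold rank).  Off the default
    path; the single zero-threshold index is the standard analysis."""
    config = config or BootstrapConfig()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("need at least one threshold")
    values, weights = [], []
    n_left = n_right = 0
    for rank, thr in enumerate(np.sort(thresholds), start=1):
        res = compute_hfli(volume, replace(config, threshold=float(thr)))
        if not res.valid:
            continue
        values.append(res.hfli)
        weights.append(rank)
        n_left, n_right = max(n_left, res.n_left_voxels), max(n_right, res.n_right_voxels)
    if not values:
        return LateralityIndex(np.nan, 0, 0, False, "no threshold yielded a valid index")
    hfli = float(np.average(values, weights=weights))
    return LateralityIndex(hfli, n_left, n_right, True)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def load_volume(
    tmap_path: str | Path,
    left_mask_path: str | Path,
    right_mask_path: str | Path,
    exclusion_path: str | Path | None = None,
) -> TMapVolume:
    """Read a t-map and masks from NIfTI files; nonzero mask voxels count."""
    values = np.asanyarray(nib.load(str(tmap_path)).dataobj, dtype=float)
    left = np.asanyarray(nib.load(str(left_mask_path)).dataobj) != 0
    right = np.asanyarray(nib.load(str(right_mask_path)).dataobj) != 0
    excl = None
    if exclusion_path is not None:
        excl = np.asanyarray(nib.load(str(exclusion_path)).dataobj) != 0
    return TMapVolume(values, left, right, excl)


def save_volume(volume: TMapVolume, directory: str | Path, stem: str = "tmap") -> dict:
    """Write volume + masks as NIfTI (identity affine); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    eye = np.eye(4)
    paths = {}
    items = {
        f"{stem}.nii": volume.values,
        f"{stem}_left.nii": volume.left_mask.astype(np.uint8),
        f"{stem}_right.nii": volume.right_mask.astype(np.uint8),
        f"{stem}_exclude.nii": volume.exclusion_mask.astype(np.uint8),
    }
    for name, arr in items.items():
        path = directory / name
        nib.save(nib.Nifti1Image(arr, eye), str(path))
        paths[name.split(".")[0].replace(f"{stem}_", "") or "tmap"] = path
    return paths
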