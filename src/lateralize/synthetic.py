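"""Synthetic cohorts, laterality-index samples and t-map volumes.

The generator reproduces the statistical structure the analysis assumes: a
handedness-balanced cohort (144 right-handers, 153 left-handers by default)
whose laterality indices follow the published handedness-specific Gaussian
mixtures, manual-preference scores drawn per (handedness, type) cell from the
published cell moments and clipped to the [-100, 100] score range, and
simple lateralized t-statistic volumes for exercising the bootstrap index.

Within a (handedness, type) cell the preference score is drawn independently
of the index value — the published summaries constrain only the cell moments,
so independence is this generator's assumption, not an observed fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap_li import TMapVolume
from .models import LH_MIXTURE, RH_MIXTURE, MixtureModel

__all__ = [
    "CohortConfig",
    "DEFAULT_MPS_MOMENTS",
    "sample_mixture",
    "generate_cohort",
    "generate_tmap",
    "write_cohort",
    "read_cohort_table",
]

# Published per-cell manual preference score moments (mean, SD) in Edinburgh
# units, keyed by (handedness, lateralization type).
DEFAULT_MPS_MOMENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("RH", "Typical"): (93.0, 11.0),
    ("RH", "Ambilateral"): (94.0, 12.0),
    ("LH", "Typical"): (-59.0, 42.0),
    ("LH", "Ambilateral"): (-73.0, 29.0),
    ("LH", "Strongly-atypical"): (-87.0, 18.0),
}

# Component-mean cutoffs mapping mixture components to types: components with
# mean above 18 are Typical, below -50 Strongly-atypical, Ambilateral between.
_TYPE_UPPER_CUT = 18.0
_TYPE_LOWER_CUT = -50.0


@dataclass
class CohortConfig:
    """Study-condition defaults: cohort composition and generating mixtures."""

    n_rh: int = 144
    n_lh: int = 153
    rh_mixture: MixtureModel = field(default_factory=lambda: RH_MIXTURE)
    lh_mixture: MixtureModel = field(default_factory=lambda: LH_MIXTURE)
    mps_moments: dict = field(default_factory=lambda: dict(DEFAULT_MPS_MOMENTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rh < 0 or self.n_lh < 0:
            raise ValueError("group sizes must be nonnegative")
        for (hand, lat), (mean, sd) in self.mps_moments.items():
            if not (-100.0 <= mean <= 100.0):
                raise ValueError(f"MPS mean for {(hand, lat)} outside [-100, 100]")
            if sd < 0:
                raise ValueError(f"MPS SD for {(hand, lat)} must be nonnegative")


def sample_mixture(model: MixtureModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` laterality-index values from a Gaussian mixture.

    Component membership is multinomial in the model weights, followed by one
    normal draw per subject.  Values are not clipped: the mixture density is
    unbounded even though measured indices live in [-100, 100].
    """
    return model.sample(n, np.random.default_rng(seed))


def _component_type(mu: float) -> str:
    if mu > _TYPE_UPPER_CUT:
        return "Typical"
    if mu < _TYPE_LOWER_CUT:
        return "Strongly-atypical"
    return "Ambilateral"


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Columns: ``subject_id``, ``handedness``, ``mps``, ``hfli``, ``gen_type``
    (the type of the mixture component that generated the subject's index —
    the ground truth that downstream classification is compared against).
    Bitwise reproducible for a fixed config seed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    frames = []
    for hand, n, model in (
        ("RH", config.n_rh, config.rh_mixture),
        ("LH", config.n_lh, config.lh_mixture),
    ):
        hfli, comp = model.sample_with_components(n, rng)
        types = [_component_type(model.means[c]) for c in comp]
        mps = np.empty(n)
        for i, lat in enumerate(types):
            try:
                mean, sd = config.mps_moments[(hand, lat)]
            except KeyError:
                raise KeyError(
                    f"no manual-preference moments configured for {(hand, lat)}"
                ) from None
            mps[i] = np.clip(rng.normal(mean, sd), -100.0, 100.0)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{hand}{i + 1:04d}" for i in range(n)],
                    "handedness": hand,
                    "mps": mps,
                    "hfli": hfli,
                    "gen_type": types,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_tmap(
    shape: tuple[int, int, int] = (16, 16, 16),
    effect_left: float = 3.0,
    effect_right: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    exclusion_fraction: float = 0.15,
) -> TMapVolume:
    """Generate a lateralized t-statistic volume with hemisphere masks.

    The volume is split at the midplane of axis 0 (lower indices = left
    hemisphere); for an odd-sized axis the midplane slab belongs to neither
    hemisphere.  Voxel values are normal around the hemisphere effect with
    ``noise_sd`` (zero gives a deterministic volume).  A posterior slab along
    axis 1 is flagged in the exclusion mask, standing in for the non-cortical
    tissue excluded from index computation.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or shape[0] < 2:
        raise ValueError("need a 3-D shape with at least 2 voxels left-right")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    nx = shape[0]
    half = nx // 2
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    left[:half] = True
    right[nx - half :] = True  # skips the midplane when nx is odd

    means = np.full(shape, 0.5 * (effect_left + effect_right))
    means[left] = effect_left
    means[right] = effect_right
    values = means if noise_sd == 0 else rng.normal(means, noise_sd)

    excl = np.zeros(shape, dtype=bool)
    n_excl = int(np.ceil(exclusion_fraction * shape[1]))
    if n_excl > 0:
        excl[:, :n_excl, :] = True
    return TMapVolume(values, left, right, excl)


# ---------------------------------------------------------------------------
# Cohort table I/O (tabular text with a header row)
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, sep="\t", index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
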