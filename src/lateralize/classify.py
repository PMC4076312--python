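"""Lateralization typing from a fitted mixture density.

The fitted mixture density is multimodal; its interior local minima are
natural cutpoints between groups of components.  Components whose separating
dip is shallow (the two left-dominant components always overlap heavily) are
pooled, which leaves three types ordered by laterality index:

* ``Typical`` — clear left-hemisphere dominance (index above the upper cut),
* ``Ambilateral`` — no clear dominance (index between the cuts, inclusive),
* ``Strongly-atypical`` — clear right-hemisphere dominance (below the lower cut).

The operational cutpoints used in the reference analysis, (-50, 18), are
shipped as :data:`REFERENCE_THRESHOLDS`; :func:`derive_thresholds` reports what
the minima of a given fitted model actually are.

A classical binary classification (index strictly positive = typical) is
computed alongside for comparison with the older literature.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import MixtureModel

__all__ = [
    "TypingThresholds",
    "TypeAssignment",
    "REFERENCE_THRESHOLDS",
    "TYPE_LABELS",
    "mixture_pdf",
    "find_local_minima",
    "find_local_maxima",
    "pool_components",
    "derive_thresholds",
    "assign_types",
    "type_summary",
]

# Labels from highest-index pool downward.
TYPE_LABELS = ("Typical", "Ambilateral", "Strongly-atypical")


@dataclass(frozen=True)
class TypingThresholds:
    """Ascending cutpoints plus type labels ordered top (highest index) first."""

    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]
    component_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cuts = self.cutpoints
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(cuts) + 1:
            raise ValueError("need exactly one more label than cutpoints")


REFERENCE_THRESHOLDS = TypingThresholds(cutpoints=(-50.0, 18.0), labels=TYPE_LABELS)


@dataclass
class TypeAssignment:
    lat_type: pd.Series  # categorical, indexed like the input
    binary_type: pd.Series  # "typical" / "atypical"
    n_excluded: int

    def counts(self) -> pd.Series:
        return self.lat_type.value_counts().reindex(
            self.lat_type.cat.categories, fill_value=0
        )


def mixture_pdf(model: MixtureModel, x) -> np.ndarray:
    """Mixture density at ``x`` (delegates to the model)."""
    return model.pdf(x)


def _extrema(
    model: MixtureModel, lo: float, hi: float, step: float, kind: str
) -> np.ndarray:
    """Sign-change scan of the log-density derivative, refined by brentq.

    ``kind="min"`` looks for - to + derivative crossings (density minima),
    ``kind="max"`` for + to - crossings.  The log-density derivative shares
    the density derivative's sign but does not underflow in deep valleys
    between well-separated components.
    """
    grid = np.arange(lo, hi + step / 2, step)
    d = model.dlogpdf(grid)
    if kind == "min":
        crossing = (d[:-1] < 0) & (d[1:] >= 0)
    else:
        crossing = (d[:-1] > 0) & (d[1:] <= 0)
    out = []
    for i in np.flatnonzero(crossing):
        a, b = grid[i], grid[i + 1]
        if d[i + 1] == 0.0:
            out.append(float(b))
        else:
            out.append(float(brentq(lambda x: model.dlogpdf(x), a, b, xtol=1e-3)))
    return np.array(out)


def find_local_minima(
    model: MixtureModel, lo: float = -100.0, hi: float = 100.0, step: float = 0.1
) -> np.ndarray:
    """Interior local minima of the mixture density on [lo, hi], ascending."""
    return _extrema(model, lo, hi, step, "min")


def find_local_maxima(
    model: MixtureModel, lo: float = -100.0, hi: float = 100.0, step: float = 0.1
) -> np.ndarray:
    return _extrema(model, lo, hi, step, "max")


def pool_components(
    model: MixtureModel,
    minima=None,
    dip_ratio_threshold: float = 0.7,
    lo: float = -100.0,
    hi: float = 100.0,
) -> TypingThresholds:
    """Turn density minima into typing thresholds, pooling across shallow dips.

    A minimum separates two modes; when the density at the minimum is at least
    ``dip_ratio_threshold`` times the lower of the two flanking modal
    densities, the dip is considered too shallow to define distinct types and
    the two pools are merged (this is what always happens between the two
    left-dominant components).  Remaining cutpoints define the types from the
    highest-mean pool (Typical) downward.
    """
    if minima is None:
        minima = find_local_minima(model, lo, hi)
    minima = np.sort(np.asarray(minima, dtype=float))
    if minima.size == 0:
        warnings.warn("density has no interior minima; single pooled type")
        return TypingThresholds((), (TYPE_LABELS[0],), _component_types(model, ()))
    # candidate peak positions: interior maxima, with component means as a
    # fallback for modes sitting on the scan boundary
    peaks = np.union1d(find_local_maxima(model, lo, hi), model.means)

    kept = []
    for m in minima:
        left_peaks = peaks[peaks < m]
        right_peaks = peaks[peaks > m]
        if left_peaks.size == 0 or right_peaks.size == 0:
            continue
        flank = min(
            float(np.max(model.pdf(left_peaks))),
            float(np.max(model.pdf(right_peaks))),
        )
        if float(model.pdf(m)) < dip_ratio_threshold * flank:
            kept.append(float(m))
    cuts = tuple(kept)
    n_types = len(cuts) + 1
    if n_types <= len(TYPE_LABELS):
        labels = TYPE_LABELS[:n_types]
    else:
        labels = TYPE_LABELS + tuple(
            f"Atypical-{i}" for i in range(4, n_types + 1)
        )
    return TypingThresholds(cuts, labels, _component_types(model, cuts))


def _component_types(model: MixtureModel, cutpoints: tuple[float, ...]) -> tuple[str, ...]:
    """Map each mixture component (descending mean) to its pooled type."""
    thr = TypingThresholds(cutpoints, _labels_for(len(cutpoints) + 1))
    return tuple(_classify_scalar(mu, thr) for mu in model.means)


def _labels_for(n_types: int) -> tuple[str, ...]:
    if n_types <= len(TYPE_LABELS):
        return TYPE_LABELS[:n_types]
    return TYPE_LABELS + tuple(f"Atypical-{i}" for i in range(4, n_types + 1))


def derive_thresholds(
    model: MixtureModel, dip_ratio_threshold: float = 0.7
) -> TypingThresholds:
    """Data-driven thresholds: minima of the fitted density after pooling."""
    return pool_components(model, dip_ratio_threshold=dip_ratio_threshold)


def _classify_scalar(x: float, thresholds: TypingThresholds) -> str:
    """Top type strictly above the last cut, bottom strictly below the first;
    values tied with a cutpoint fall into the adjacent middle type."""
    cuts = thresholds.cutpoints
    labels = thresholds.labels  # top first
    if not cuts:
        return labels[0]
    if x > cuts[-1]:
        return labels[0]
    if x < cuts[0]:
        return labels[-1]
    # interior: count how many of the remaining upper cutpoints x exceeds
    inner = cuts[1:-1]
    rank = int(np.sum(x > np.asarray(inner))) if inner else 0
    return labels[len(cuts) - 1 - rank]


def assign_types(
    hfli, thresholds: TypingThresholds = REFERENCE_THRESHOLDS
) -> TypeAssignment:
    """Assign a lateralization type and binary class per laterality index.

    Binary classification uses the zero threshold with strict positivity:
    an index of exactly 0 is atypical.  Missing indices are excluded and
    counted.
    """
    hfli = pd.Series(np.asarray(hfli, dtype=float))
    valid = hfli.notna()
    cats = list(thresholds.labels)
    lat = pd.Series(
        pd.Categorical([None] * len(hfli), categories=cats), index=hfli.index
    )
    lat[valid] = [_classify_scalar(x, thresholds) for x in hfli[valid]]
    binary = pd.Series(
        pd.Categorical([None] * len(hfli), categories=["typical", "atypical"]),
        index=hfli.index,
    )
    binary[valid] = np.where(hfli[valid] > 0, "typical", "atypical")
    return TypeAssignment(lat, binary, int((~valid).sum()))


def type_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-handedness, per-type summary: N, %, index and preference moments.

    Expects columns ``handedness``, ``hfli``, ``lat_type`` and optionally
    ``mps``; SDs use the n-1 convention, matching how cohort tables are
    usually reported.
    """
    rows = []
    for hand, sub in cohort.groupby("handedness", observed=True):
        n_hand = len(sub)
        for lat, cell in sub.groupby("lat_type", observed=False):
            n = len(cell)
            row = {
                "handedness": hand,
                "lat_type": lat,
                "N": n,
                "pct": 100.0 * n / n_hand if n_hand else np.nan,
                "hfli_mean": cell["hfli"].mean(),
                "hfli_sd": cell["hfli"].std(ddof=1),
            }
            if "mps" in cell:
                row["mps_mean"] = cell["mps"].mean()
                row["mps_sd"] = cell["mps"].std(ddof=1)
            rows.append(row)
    return pd.DataFrame(rows)
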