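"""Univariate Gaussian mixture models for laterality-index densities.

A hemispheric functional laterality index (HFLI) computed over a cohort is
typically multimodal: most subjects cluster at clearly positive (left-dominant)
values, a smaller group sits near zero, and a rare group is strongly negative
(right-dominant).  Mixtures of univariate Gaussians are the standard way to
describe such densities, and everything downstream (model selection, typing
thresholds, synthetic cohorts) works on the :class:`MixtureModel` container
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "RH_MIXTURE",
    "LH_MIXTURE",
    "WHOLE_SAMPLE_MIXTURE",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: mean and SD in index units, weight in (0, 1]."""

    mu: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError(f"component mean must be finite, got {self.mu}")
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise ValueError(f"component SD must be positive, got {self.sigma}")
        if not (0 < self.weight <= 1):
            raise ValueError(f"component weight must be in (0, 1], got {self.weight}")


class MixtureModel:
    """Ordered finite mixture of univariate Gaussians.

    Components are stored in descending order of mean, so index 0 is always
    the most leftward-dominant (highest laterality index) component.  Weights
    must sum to one within ``1e-9``; use :meth:`from_arrays` with
    ``normalize=True`` to renormalize printed weights that only sum to one
    after rounding.
    """

    def __init__(self, components: Iterable[GaussianComponent]):
        comps = sorted(components, key=lambda c: -c.mu)
        if not comps:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"component weights must sum to 1 within {_WEIGHT_TOL}; got {total!r}"
            )
        self.components: tuple[GaussianComponent, ...] = tuple(comps)

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        means: Sequence[float],
        sds: Sequence[float],
        weights: Sequence[float],
        normalize: bool = False,
    ) -> "MixtureModel":
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if not (means.shape == sds.shape == weights.shape) or means.ndim != 1:
            raise ValueError("means, sds and weights must be 1-D and equally long")
        if normalize:
            weights = weights / weights.sum()
        return cls(
            GaussianComponent(m, s, w) for m, s, w in zip(means, sds, weights)
        )

    # -- basic accessors ------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(
            f"({c.mu:.4g}, {c.sigma:.4g}, {c.weight:.4g})" for c in self.components
        )
        return f"MixtureModel[{parts}]"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixtureModel):
            return NotImplemented
        return self.components == other.components

    # -- density and moments --------------------------------------------

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lp = (
            np.log(self.weights)
            + stats.norm.logpdf(x[..., None], self.means, self.sds)
        )
        return logsumexp(lp, axis=-1)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def dpdf(self, x) -> np.ndarray:
        """Analytic first derivative of the mixture density."""
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        comp = self.weights * stats.norm.pdf(x[..., None], self.means, self.sds)
        return np.sum(comp * (-z / self.sds), axis=-1)

    def dlogpdf(self, x) -> np.ndarray:
        """Derivative of the log-density: responsibility-weighted average of
        the per-component scores.  Shares the sign of the density derivative
        but stays finite where the density itself underflows, which matters
        when locating minima between well-separated components."""
        x = np.asarray(x, dtype=float)
        lp = np.log(self.weights) + stats.norm.logpdf(
            x[..., None], self.means, self.sds
        )
        resp = np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))
        score = -(x[..., None] - self.means) / self.sds**2
        return np.sum(resp * score, axis=-1)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.weights * stats.norm.cdf(x[..., None], self.means, self.sds), axis=-1
        )

    def mean(self) -> float:
        return float(np.sum(self.weights * self.means))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum(self.weights * (self.sds**2 + self.means**2)) - m**2)

    # -- sampling --------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values: multinomial component membership, then a normal
        draw per component.  Values are not clipped to the index range."""
        if n < 0:
            raise ValueError("n must be nonnegative")
        if n == 0:
            return np.empty(0)
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])

    def sample_with_components(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Like :meth:`sample` but also return the component index per draw."""
        if n < 0:
            raise ValueError("n must be nonnegative")
        if n == 0:
            return np.empty(0), np.empty(0, dtype=int)
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp]), comp

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MixtureModel":
        return cls.from_arrays(d["means"], d["sds"], d["weights"])

    def to_text(self) -> str:
        """Key-value text serialization, one ``key = values`` line per field."""
        fmt = lambda a: " ".join(repr(float(v)) for v in a)
        return (
            f"n_components = {self.n_components}\n"
            f"means = {fmt(self.means)}\n"
            f"sds = {fmt(self.sds)}\n"
            f"weights = {fmt(self.weights)}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "MixtureModel":
        fields: dict[str, list[float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = [float(v) for v in value.split()]
        return cls.from_arrays(fields["means"], fields["sds"], fields["weights"])


# Published optimal mixture parameters for the two handedness groups and the
# pooled sample.  Printed weights sum to 1 only after rounding, hence
# normalize=True.
RH_MIXTURE = MixtureModel.from_arrays(
    means=[65.3, 43.9, 4.4],
    sds=[8.1, 5.3, 17.7],
    weights=[0.674, 0.203, 0.122],
    normalize=True,
)

LH_MIXTURE = MixtureModel.from_arrays(
    means=[71.5, 52.0, -8.2, -63.6],
    sds=[6.0, 10.6, 16.4, 5.4],
    weights=[0.367, 0.413, 0.154, 0.065],
    normalize=True,
)

WHOLE_SAMPLE_MIXTURE = MixtureModel.from_arrays(
    means=[67.0, 46.0, -4.0, -63.0],
    sds=[7.9, 8.4, 19.3, 5.3],
    weights=[0.575, 0.257, 0.133, 0.033],
    normalize=True,
)
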