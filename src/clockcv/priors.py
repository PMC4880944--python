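"""Prior distributions for the hierarchical model.

All defaults are proper (they integrate to 1), which stepping-stone
marginal-likelihood estimation requires.  Every prior can be overridden
per-parameter in :class:`PriorSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Prior",
    "LogNormalPrior",
    "ExponentialPrior",
    "GammaPrior",
    "LaplacePrior",
    "NormalPrior",
    "PointMassPrior",
    "ImproperUniformPrior",
    "PriorSet",
    "default_priors",
]


class Prior:
    """Interface: log_pdf(x), sample(rng); `proper` flags integrability."""

    proper: bool = True

    def log_pdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class LogNormalPrior(Prior):
    """Lognormal with log-space location `mu` (real-space median e^mu)."""

    mu: float = 0.0
    sigma: float = 1.0
    proper: bool = True

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (np.log(x) - self.mu) / self.sigma
        return -0.5 * z * z - np.log(x * self.sigma) - 0.5 * np.log(2 * np.pi)

    def sample(self, rng):
        return float(rng.lognormal(self.mu, self.sigma))


@dataclass(frozen=True)
class ExponentialPrior(Prior):
    mean: float = 1.0
    proper: bool = True

    def log_pdf(self, x: float) -> float:
        if x < 0:
            return -np.inf
        return -x / self.mean - np.log(self.mean)

    def sample(self, rng):
        return float(rng.exponential(self.mean))


@dataclass(frozen=True)
class GammaPrior(Prior):
    shape: float = 2.0
    scale: float = 0.5
    proper: bool = True

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return float(stats.gamma.logpdf(x, self.shape, scale=self.scale))

    def sample(self, rng):
        return float(rng.gamma(self.shape, self.scale))


@dataclass(frozen=True)
class LaplacePrior(Prior):
    loc: float = 0.0
    scale: float = 1.0
    proper: bool = True

    def log_pdf(self, x: float) -> float:
        return -abs(x - self.loc) / self.scale - np.log(2 * self.scale)

    def sample(self, rng):
        return float(rng.laplace(self.loc, self.scale))


@dataclass(frozen=True)
class NormalPrior(Prior):
    loc: float = 0.0
    scale: float = 1.0
    proper: bool = True

    def log_pdf(self, x: float) -> float:
        z = (x - self.loc) / self.scale
        return -0.5 * z * z - np.log(self.scale) - 0.5 * np.log(2 * np.pi)

    def sample(self, rng):
        return float(rng.normal(self.loc, self.scale))


@dataclass(frozen=True)
class PointMassPrior(Prior):
    """Degenerate prior pinning a parameter to a single value."""

    value: float = 0.0
    proper: bool = True

    def log_pdf(self, x: float) -> float:
        return 0.0 if x == self.value else -np.inf

    def sample(self, rng):
        return self.value


@dataclass(frozen=True)
class ImproperUniformPrior(Prior):
    """Flat density over the real line; NOT integrable.

    Provided so that configurations with improper priors can be
    represented — stepping-stone refuses them explicitly.
    """

    proper: bool = False

    def log_pdf(self, x: float) -> float:
        return 0.0

    def sample(self, rng):
        raise ValueError("cannot sample from an improper prior")


@dataclass(frozen=True)
class PriorSet:
    """Hyperpriors for every free scalar of the hierarchical model.

    Defaults: clock mean rate lognormal with real-space median 1e-3 and
    log-sd 1.5; UCLN log-space sd exponential(mean 0.3); N0 lognormal
    (median 1, log-sd 2); growth rate Laplace(0, 1); GTR
    exchangeabilities i.i.d. gamma; base frequencies flat Dirichlet
    (handled in the sampler); Γ shape lognormal(median 1, log-sd 1).
    """

    clock_mean: Prior = field(
        default_factory=lambda: LogNormalPrior(mu=float(np.log(1e-3)), sigma=1.5)
    )
    clock_sd: Prior = field(default_factory=lambda: ExponentialPrior(mean=0.3))
    pop_size: Prior = field(default_factory=lambda: LogNormalPrior(mu=0.0, sigma=2.0))
    growth_rate: Prior = field(default_factory=lambda: LaplacePrior(loc=0.0, scale=1.0))
    gtr_rate: Prior = field(default_factory=lambda: GammaPrior(shape=2.0, scale=0.5))
    gamma_shape: Prior = field(default_factory=lambda: LogNormalPrior(mu=0.0, sigma=1.0))

    def all_proper(self) -> bool:
        return all(
            p.proper
            for p in (
                self.clock_mean,
                self.clock_sd,
                self.pop_size,
                self.growth_rate,
                self.gtr_rate,
                self.gamma_shape,
            )
        )


def default_priors() -> PriorSet:
    return PriorSet()
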