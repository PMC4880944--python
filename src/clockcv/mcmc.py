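"""Posterior sampling for the hierarchical clock/coalescent model.

The hierarchical model couples four components: a coalescent tree prior
(constant-size or exponential-growth), a molecular clock (strict,
uncorrelated-lognormal or uncorrelated-exponential), a nucleotide
substitution model (JC or GTR+Γ) and the phylogenetic likelihood.
Sampling is plain Metropolis-Hastings over node ages, branch rates,
clock hyperparameters, demographic and substitution parameters, with an
optional narrow-exchange topology move.

The public surface follows a Model/Results pattern:
``HierarchicalClockModel(alignment, config).fit(settings)`` returns a
:class:`ClockFitResults` wrapping the posterior trace, per-parameter
effective sample sizes, summaries and cross-validation scoring hooks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .alignment import Alignment
from .likelihood import (
    SubstitutionModel,
    _mean_over_categories,
    _prune_category,
    _tip_partials,
    discrete_gamma_multipliers,
    transition_matrices,
)
from .priors import PointMassPrior, Prior, PriorSet, default_priors
from .simulate import ClockModel, DemographicModel, coalescent_intensity
from .trees import BranchRateMap, TimeTree, _postorder as _tree_postorder

__all__ = [
    "HierarchicalModelConfig",
    "MCMCSettings",
    "PosteriorTrace",
    "HierarchicalClockModel",
    "ClockFitResults",
    "coalescent_log_density",
    "clock_log_density",
    "mcmc_run",
    "effective_sample_size",
    "EssValue",
    "extend_until_converged",
    "stepping_stone_logml",
    "SteppingStoneResult",
    "ImproperPriorError",
    "n_free_parameters",
]


class ImproperPriorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def _coalescent_log_density_arrays(
    tip_ages: np.ndarray,
    node_ages: np.ndarray,
    pop_size: float,
    growth_rate: float,
) -> float:
    """Serial-coalescent log density with N(t) = N0 e^{-r t} (t backwards).

    Each inter-event interval with k active lineages contributes
    -[k(k-1)/2] (Λ(t1) - Λ(t0)) with Λ the cumulative pairwise
    intensity; each coalescence at t_c contributes -ln N(t_c).
    """
    if pop_size <= 0:
        raise ValueError("population size must be positive")
    demo = DemographicModel(
        kind="EGC" if growth_rate != 0 else "CSC",
        pop_size=pop_size,
        growth_rate=growth_rate,
    )
    ages = np.concatenate([tip_ages, node_ages])
    delta = np.concatenate(
        [np.ones_like(tip_ages), -np.ones_like(node_ages)]
    )
    # sampling events before coalescences at equal times
    order = np.lexsort((-delta, ages))
    ages, delta = ages[order], delta[order]
    k = np.cumsum(delta)  # lineages active after each event
    lam = coalescent_intensity(ages, demo)
    pairs = k[:-1] * (k[:-1] - 1.0) / 2.0
    log_dens = -float(pairs @ np.diff(lam))
    coal = delta < 0
    # -ln N(t_c) = -ln N0 + r t_c
    log_dens += float(
        np.sum(-np.log(pop_size) + growth_rate * ages[coal])
    )
    return log_dens


def coalescent_log_density(tree: TimeTree, demographic: DemographicModel) -> float:
    """Log prior density of a genealogy under the coalescent."""
    tip_ages = tree.age[: tree.n_tips]
    node_ages = tree.age[tree.n_tips :]
    return _coalescent_log_density_arrays(
        tip_ages, node_ages, demographic.pop_size, demographic.growth_rate
    )


def _lognormal_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (np.log(x) - mu) / sigma
    return -0.5 * z * z - np.log(x * sigma) - 0.5 * np.log(2 * np.pi)


def _clock_log_density_arrays(
    rates: np.ndarray, kind: str, mean_rate: float, sd_log: float
) -> float:
    """Log density of off-root branch rates given clock hyperparameters.

    For UCLN, ``sd_log`` is the log-space standard deviation S and the
    location is chosen so the real-space mean equals ``mean_rate``.
    """
    if np.any(rates <= 0):
        raise ValueError("branch rates must be positive")
    if kind == "SC":
        return 0.0
    if kind == "UCLN":
        if sd_log <= 0:
            return -np.inf
        mu = np.log(mean_rate) - sd_log**2 / 2.0
        return float(np.sum(_lognormal_logpdf(rates, mu, sd_log)))
    if kind == "UCED":
        return float(np.sum(-rates / mean_rate - np.log(mean_rate)))
    raise ValueError(f"unknown clock kind {kind!r}")


def clock_log_density(
    rates: BranchRateMap,
    clock: ClockModel,
    root: Optional[int] = None,
) -> float:
    """Log density of a branch-rate map under its clock model.

    ``root`` (node index), when given, excludes the root's unused rate
    entry.  For UCLN the ``clock``'s real-space mean/sd are converted to
    log-space parameters by moment matching.
    """
    r = rates.rate
    if root is not None:
        r = np.delete(r, root)
    if clock.kind == "UCLN":
        _, s = clock.lognormal_params()
        return _clock_log_density_arrays(r, "UCLN", clock.mean_rate, s)
    return _clock_log_density_arrays(r, clock.kind, clock.mean_rate, 0.0)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierarchicalModelConfig:
    """One (clock, demographic, substitution) model combination."""

    clock: str = "SC"
    demographic: str = "CSC"
    substitution: SubstitutionModel = field(default_factory=SubstitutionModel)
    estimate_substitution: bool = False
    topology_fixed: bool = True
    estimate_ages: bool = True
    use_likelihood: bool = True
    priors: PriorSet = field(default_factory=default_priors)

    def __post_init__(self):
        if self.clock not in ("SC", "UCLN", "UCED"):
            raise ValueError(f"unknown clock {self.clock!r}")
        if self.demographic not in ("CSC", "EGC"):
            raise ValueError(f"unknown demographic model {self.demographic!r}")

    @property
    def label(self) -> str:
        return f"{self.clock}+{self.demographic}"


@dataclass(frozen=True)
class MCMCSettings:
    """Chain-control settings (defaults mirror the study's BEAST runs)."""

    chain_length: int = 10_000_000
    sample_every: int = 5_000
    burnin_fraction: float = 0.10
    ess_threshold: float = 200.0
    max_doublings: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.chain_length % self.sample_every != 0:
            raise ValueError("sample_every must divide chain_length")


def n_free_parameters(config: HierarchicalModelConfig, n_taxa: int) -> int:
    """Count of free scalar parameters (tie-breaking: fewer wins)."""
    n = 1  # clock mean rate
    if config.clock == "UCLN":
        n += 1 + (2 * n_taxa - 2)  # sd + per-branch rates
    elif config.clock == "UCED":
        n += 2 * n_taxa - 2
    n += 1  # pop size
    if config.demographic == "EGC":
        n += 1
    if config.estimate_ages:
        n += n_taxa - 1
    if config.estimate_substitution and config.substitution.kind == "GTR":
        n += 6 + 3 + (1 if config.substitution.gamma_shape is not None else 0)
    return n


# ---------------------------------------------------------------------------
# Sampler state
# ---------------------------------------------------------------------------

@dataclass
class _State:
    parent: np.ndarray
    children: np.ndarray
    postorder: np.ndarray
    root: int
    age: np.ndarray
    clock_mean: float
    clock_sd: float  # UCLN log-space S (unused otherwise)
    branch_rates: Optional[np.ndarray]
    pop_size: float
    growth_rate: float
    freqs: np.ndarray
    exch: np.ndarray
    alpha: Optional[float]
    log_lik: float = np.nan
    log_prior: float = np.nan

    def copy(self) -> "_State":
        return _State(
            self.parent,
            self.children,
            self.postorder,
            self.root,
            self.age.copy(),
            self.clock_mean,
            self.clock_sd,
            None if self.branch_rates is None else self.branch_rates.copy(),
            self.pop_size,
            self.growth_rate,
            self.freqs.copy(),
            self.exch.copy(),
            self.alpha,
        )


class _ModelContext:
    """Precomputed immutable pieces shared across the chain."""

    def __init__(
        self,
        alignment: Alignment,
        config: HierarchicalModelConfig,
        tree: TimeTree,
    ):
        self.config = config
        self.alignment = alignment
        self.tree = tree
        tree_set, aln_set = set(tree.tip_names), set(alignment.taxa)
        if tree_set != aln_set:
            raise ValueError(
                f"taxa differ between tree and alignment: {sorted(tree_set ^ aln_set)}"
            )
        row = {name: i for i, name in enumerate(alignment.taxa)}
        order = [row[name] for name in tree.tip_names]
        self.tip_partials = _tip_partials(alignment.patterns[order])
        self.pattern_weights = alignment.pattern_weights
        self.tip_ages = tree.age[: tree.n_tips].copy()
        self.n_tips = tree.n_tips
        self.n_nodes = tree.n_nodes

    def subst_model(self, st: _State) -> SubstitutionModel:
        base = self.config.substitution
        if not self.config.estimate_substitution:
            return base
        return SubstitutionModel(
            kind=base.kind,
            exchangeabilities=st.exch,
            base_freqs=st.freqs,
            gamma_shape=st.alpha,
            n_categories=base.n_categories,
        )

    def branch_lengths(self, st: _State) -> np.ndarray:
        dur = np.zeros(self.n_nodes)
        mask = st.parent >= 0
        dur[mask] = st.age[st.parent[mask]] - st.age[mask]
        if self.config.clock == "SC":
            return dur * st.clock_mean
        return dur * st.branch_rates

    def log_likelihood(self, st: _State) -> float:
        if not self.config.use_likelihood:
            return 0.0
        model = self.subst_model(st)
        blen = self.branch_lengths(st)
        if model.gamma_shape is None:
            mults = np.ones(1)
        else:
            mults = discrete_gamma_multipliers(model.gamma_shape, model.n_categories)
        per_cat = np.empty((len(mults), self.tip_partials.shape[1]))
        for c, r in enumerate(mults):
            pmats = transition_matrices(model, blen * r)
            per_cat[c] = _prune_category(
                self.n_tips,
                st.children,
                st.postorder,
                st.root,
                pmats,
                self.tip_partials,
                model.base_freqs,
            )
        logl = _mean_over_categories(per_cat)
        return float(self.pattern_weights @ logl)

    def log_prior(self, st: _State) -> float:
        cfg = self.config
        pri = cfg.priors
        # tree validity: every non-root branch has non-negative duration
        mask = st.parent >= 0
        dur = st.age[st.parent[mask]] - st.age[mask]
        if np.any(dur < 0) or st.pop_size <= 0 or st.clock_mean <= 0:
            return -np.inf
        lp = pri.clock_mean.log_pdf(st.clock_mean)
        if cfg.clock == "UCLN":
            if st.clock_sd <= 0:
                return -np.inf
            lp += pri.clock_sd.log_pdf(st.clock_sd)
            rates = np.delete(st.branch_rates, st.root)
            if np.any(rates <= 0):
                return -np.inf
            lp += _clock_log_density_arrays(
                rates, "UCLN", st.clock_mean, st.clock_sd
            )
        elif cfg.clock == "UCED":
            rates = np.delete(st.branch_rates, st.root)
            if np.any(rates <= 0):
                return -np.inf
            lp += _clock_log_density_arrays(rates, "UCED", st.clock_mean, 0.0)
        lp += pri.pop_size.log_pdf(st.pop_size)
        if cfg.demographic == "EGC":
            lp += pri.growth_rate.log_pdf(st.growth_rate)
        node_ages = st.age[self.n_tips :]
        lp += _coalescent_log_density_arrays(
            self.tip_ages, node_ages, st.pop_size, st.growth_rate
        )
        if cfg.estimate_substitution:
            lp += float(sum(pri.gtr_rate.log_pdf(x) for x in st.exch))
            lp += math.lgamma(4)  # flat Dirichlet on frequencies
            if st.alpha is not None:
                lp += pri.gamma_shape.log_pdf(st.alpha)
        return float(lp)


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------
# Each move returns (new_state, log_hastings); proposal densities for the
# testable moves are exposed for the detailed-balance smoke test.

_LAMBDA = 0.7  # multiplier window


def _multiplier(x: float, rng: np.random.Generator) -> tuple[float, float]:
    m = math.exp(_LAMBDA * (rng.random() - 0.5))
    return x * m, math.log(m)


class _Move:
    name = "move"

    def propose(self, st: _State, ctx: _ModelContext, rng) -> tuple[_State, float]:
        raise NotImplementedError


class ScaleInternalAges(_Move):
    name = "scale_ages"

    def propose(self, st, ctx, rng):
        new = st.copy()
        m = math.exp(_LAMBDA * (rng.random() - 0.5))
        k = ctx.n_nodes - ctx.n_tips
        new.age[ctx.n_tips :] *= m
        return new, k * math.log(m)


class SlideNodeAge(_Move):
    """Uniform slide of one internal node within (oldest child, parent)."""

    name = "slide_age"

    def propose(self, st, ctx, rng):
        new = st.copy()
        node = int(rng.integers(ctx.n_tips, ctx.n_nodes))
        kids = st.children[node - ctx.n_tips]
        lo = float(st.age[kids].max())
        if node == st.root:
            x, lh = _multiplier(st.age[node] - lo, rng)
            new.age[node] = lo + x
            return new, lh
        hi = float(st.age[st.parent[node]])
        new.age[node] = lo + rng.random() * (hi - lo)
        return new, 0.0


class ScalarMultiplier(_Move):
    def __init__(self, name: str, attr: str):
        self.name = name
        self.attr = attr

    def propose(self, st, ctx, rng):
        new = st.copy()
        x, lh = _multiplier(getattr(st, self.attr), rng)
        setattr(new, self.attr, x)
        return new, lh

    # for the detailed-balance check
    def log_proposal_density(self, x: float, y: float) -> float:
        # y = x * exp(lambda (u - 1/2)), u ~ U(0,1)  =>  density 1/(lambda y)
        if y <= 0 or abs(math.log(y / x)) > _LAMBDA / 2:
            return -np.inf
        return -math.log(_LAMBDA * y)


class GrowthWalk(_Move):
    name = "growth_walk"
    step = 0.5

    def propose(self, st, ctx, rng):
        new = st.copy()
        new.growth_rate = st.growth_rate + rng.normal(0.0, self.step)
        return new, 0.0

    def log_proposal_density(self, x: float, y: float) -> float:
        z = (y - x) / self.step
        return -0.5 * z * z - math.log(self.step) - 0.5 * math.log(2 * math.pi)


class BranchRateMultiplier(_Move):
    name = "branch_rate"

    def propose(self, st, ctx, rng):
        new = st.copy()
        node = int(rng.integers(ctx.n_nodes - 1))
        if node >= st.root:
            node += 1  # skip the root slot
        x, lh = _multiplier(st.branch_rates[node], rng)
        new.branch_rates[node] = x
        return new, lh


class AllRatesScale(_Move):
    name = "all_rates"

    def propose(self, st, ctx, rng):
        new = st.copy()
        m = math.exp(_LAMBDA * (rng.random() - 0.5))
        new.branch_rates = st.branch_rates * m
        new.branch_rates[st.root] = st.branch_rates[st.root]
        return new, (ctx.n_nodes - 1) * math.log(m)


class FrequencyExchange(_Move):
    """Move mass eps between two frequencies (symmetric proposal)."""

    name = "freq_exchange"
    eps = 0.05

    def propose(self, st, ctx, rng):
        new = st.copy()
        i, j = rng.choice(4, size=2, replace=False)
        d = rng.random() * self.eps
        new.freqs[i] += d
        new.freqs[j] -= d
        if new.freqs[j] <= 0 or new.freqs[i] >= 1:
            new.freqs = st.freqs.copy()  # will be rejected via prior
            new.freqs[j] = -1.0
        return new, 0.0


class ExchMultiplier(_Move):
    name = "exch_rate"

    def propose(self, st, ctx, rng):
        new = st.copy()
        i = int(rng.integers(6))
        x, lh = _multiplier(st.exch[i], rng)
        new.exch[i] = x
        return new, lh


class AlphaMultiplier(_Move):
    name = "gamma_shape"

    def propose(self, st, ctx, rng):
        new = st.copy()
        x, lh = _multiplier(st.alpha, rng)
        new.alpha = x
        return new, lh


class UclnSdRescale(_Move):
    """Multiplier on the UCLN sd with branch rates following.

    Branch rates are deterministic functions of their standardised
    log-scores z_i = (ln r_i - mu)/S, which are held fixed while S (and
    hence mu = ln mean - S^2/2) changes.  This traverses the hierarchical
    funnel that defeats componentwise moves when S is small.
    """

    name = "ucln_sd_rescale"

    def propose(self, st, ctx, rng):
        new = st.copy()
        m = math.exp(_LAMBDA * (rng.random() - 0.5))
        s_old, s_new = st.clock_sd, st.clock_sd * m
        mu_old = math.log(st.clock_mean) - s_old**2 / 2.0
        mu_new = math.log(st.clock_mean) - s_new**2 / 2.0
        log_r = np.log(st.branch_rates)
        z = (log_r - mu_old) / s_old
        new_log_r = mu_new + s_new * z
        new.branch_rates = np.exp(new_log_r)
        new.branch_rates[st.root] = st.branch_rates[st.root]
        new.clock_sd = s_new
        n_br = ctx.n_nodes - 1
        mask = np.arange(ctx.n_nodes) != st.root
        log_jac = float(np.sum(new_log_r[mask] - log_r[mask])) + n_br * math.log(m)
        return new, math.log(m) + log_jac


class RateAgeUpDown(_Move):
    """Scale rates up and internal ages down jointly.

    Branch lengths in substitutions are invariant, so this walks along
    the rate-time ridge that otherwise dominates the autocorrelation
    time of the clock rate and the root age.
    """

    name = "rate_age_updown"
    window = 1.2

    def propose(self, st, ctx, rng):
        new = st.copy()
        m = math.exp(self.window * (rng.random() - 0.5))
        new.clock_mean = st.clock_mean * m
        n_up = 1
        if st.branch_rates is not None:
            new.branch_rates = st.branch_rates * m
            n_up += ctx.n_nodes - 1
        k = ctx.n_nodes - ctx.n_tips
        new.age[ctx.n_tips :] /= m
        return new, (n_up - k) * math.log(m)


class NarrowExchange(_Move):
    """Swap a node with its aunt when ages permit (symmetric)."""

    name = "narrow_exchange"

    def propose(self, st, ctx, rng):
        new = st.copy()
        node = int(rng.integers(ctx.n_tips, ctx.n_nodes))
        if node == st.root:
            return new, -np.inf
        new.parent = st.parent.copy()
        new.children = st.children.copy()
        p = st.parent[node]
        sibs = st.children[p - ctx.n_tips]
        sib = sibs[0] if sibs[1] == node else sibs[1]
        kids = st.children[node - ctx.n_tips]
        child = kids[int(rng.integers(2))]
        # swap `sib` and `child`; valid only if node can hold sib below it
        if st.age[node] <= st.age[sib]:
            return new, -np.inf
        new.parent[sib] = node
        new.parent[child] = p
        new.children[p - ctx.n_tips] = [child if c == sib else c for c in sibs]
        new.children[node - ctx.n_tips] = [sib if c == child else c for c in kids]
        new.postorder = _tree_postorder(ctx.n_tips, new.children, st.root)
        return new, 0.0


def _build_moves(config: HierarchicalModelConfig) -> list[tuple[_Move, float]]:
    pri = config.priors
    pinned = lambda p: isinstance(p, PointMassPrior)
    moves: list[tuple[_Move, float]] = []
    if config.estimate_ages:
        moves.append((ScaleInternalAges(), 1.0))
        moves.append((SlideNodeAge(), 4.0))
        if not pinned(pri.clock_mean):
            moves.append((RateAgeUpDown(), 2.0))
    if not pinned(pri.clock_mean):
        moves.append((ScalarMultiplier("clock_mean", "clock_mean"), 1.0))
    if config.clock == "UCLN" and not pinned(pri.clock_sd):
        moves.append((ScalarMultiplier("clock_sd", "clock_sd"), 1.0))
        moves.append((UclnSdRescale(), 1.0))
    if config.clock in ("UCLN", "UCED"):
        moves.append((BranchRateMultiplier(), 4.0))
        moves.append((AllRatesScale(), 1.0))
    if not pinned(pri.pop_size):
        moves.append((ScalarMultiplier("pop_size", "pop_size"), 1.0))
    if config.demographic == "EGC" and not pinned(pri.growth_rate):
        moves.append((GrowthWalk(), 1.0))
    if config.estimate_substitution:
        moves.append((FrequencyExchange(), 1.0))
        moves.append((ExchMultiplier(), 1.0))
        if config.substitution.gamma_shape is not None:
            moves.append((AlphaMultiplier(), 1.0))
    if not config.topology_fixed:
        moves.append((NarrowExchange(), 2.0))
    return moves


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

class EssValue(float):
    """ESS value; ``degenerate`` is True for a constant input series."""

    degenerate: bool = False

    def __new__(cls, value: float, degenerate: bool = False):
        obj = super().__new__(cls, value)
        obj.degenerate = degenerate
        return obj


def effective_sample_size(series) -> EssValue:
    """ESS = n / (1 + 2 Σ ρ̂_k) with Geyer initial-monotone truncation.

    Autocorrelations are summed in consecutive pairs, truncated at the
    first non-positive pair sum and forced non-increasing.  A constant
    series yields ESS 1 with ``degenerate=True``.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    v = x.var()
    if np.all(x == x[0]) or not np.isfinite(v):
        return EssValue(1.0, degenerate=True)
    xc = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # pair sums Γ_m = ρ_{2m} + ρ_{2m+1}
    max_pairs = (n - 1) // 2
    tau = 0.0
    prev = np.inf
    for m in range(max_pairs):
        g = rho[2 * m] + rho[2 * m + 1]
        if g <= 0:
            break
        g = min(g, prev)
        prev = g
        tau += 2.0 * g
    tau = max(tau - 1.0, 1.0 / n)
    return EssValue(min(n / tau, float(n)))


@dataclass
class PosteriorTrace:
    """Retained post-burn-in MCMC samples.

    ``scalars`` has one row per retained sample (step, log_posterior,
    log_likelihood, log_prior and every scalar parameter); ``ages`` /
    ``branch_rates`` / ``parents`` carry the per-sample tree state.
    """

    scalars: pd.DataFrame
    ages: list[np.ndarray]
    branch_rates: list[Optional[np.ndarray]]
    parents: list[np.ndarray]
    config: HierarchicalModelConfig
    settings: MCMCSettings
    tip_names: list[str]
    acceptance: dict[str, float]
    flags: list[str] = field(default_factory=list)
    n_doublings: int = 0
    ess: dict[str, float] = field(default_factory=dict)
    _final_state: Optional[_State] = None
    _ctx: Optional[_ModelContext] = None
    _rng: Optional[np.random.Generator] = None

    def __len__(self) -> int:
        return len(self.scalars)

    @property
    def parameter_columns(self) -> list[str]:
        skip = {"step", "log_posterior", "log_likelihood", "log_prior"}
        return [c for c in self.scalars.columns if c not in skip]

    def compute_ess(self) -> dict[str, float]:
        self.ess = {}
        for col in self.parameter_columns + ["log_likelihood"]:
            vals = self.scalars[col].to_numpy()
            if len(vals) >= 10:
                e = effective_sample_size(vals)
                # a pinned (constant) quantity is not a mixing failure
                self.ess[col] = float(len(vals)) if e.degenerate else float(e)
        return self.ess

    @property
    def min_ess(self) -> float:
        if not self.ess:
            self.compute_ess()
        return min(self.ess.values()) if self.ess else float("inf")

    def sample_tree(self, i: int) -> TimeTree:
        return TimeTree(
            self.tip_names,
            self.parents[i],
            self.ages[i],
            allow_zero_branches=True,
        )

    def sample_rates(self, i: int) -> BranchRateMap:
        if self.branch_rates[i] is None:
            r = self.scalars["clock_mean"].iloc[i]
            n = len(self.ages[i])
            return BranchRateMap(np.full(n, r), clock_kind="SC")
        return BranchRateMap(self.branch_rates[i], clock_kind=self.config.clock)

    def sample_subst_model(self, i: int) -> SubstitutionModel:
        base = self.config.substitution
        if not self.config.estimate_substitution:
            return base
        row = self.scalars.iloc[i]
        return SubstitutionModel(
            kind=base.kind,
            exchangeabilities=[row[f"exch_{p}"] for p in _EXCH_NAMES],
            base_freqs=np.array([row[f"freq_{b}"] for b in "ACGT"]),
            gamma_shape=row.get("gamma_shape", base.gamma_shape),
            n_categories=base.n_categories,
        )

    def to_tsv(self, path: str) -> None:
        self.scalars.to_csv(path, sep="\t", index=False)


_EXCH_NAMES = ["AC", "AG", "AT", "CG", "CT", "GT"]


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

def _initial_value(prior: Prior) -> float:
    from .priors import (
        ExponentialPrior,
        GammaPrior,
        LaplacePrior,
        LogNormalPrior,
        NormalPrior,
    )

    if isinstance(prior, PointMassPrior):
        return prior.value
    if isinstance(prior, LogNormalPrior):
        return math.exp(prior.mu)
    if isinstance(prior, ExponentialPrior):
        return prior.mean
    if isinstance(prior, GammaPrior):
        return prior.shape * prior.scale
    if isinstance(prior, (LaplacePrior, NormalPrior)):
        return prior.loc
    return 1.0


def _initial_state(ctx: _ModelContext, rng: np.random.Generator) -> _State:
    cfg = ctx.config
    tree = ctx.tree
    pri = cfg.priors
    clock_mean = _initial_value(pri.clock_mean)
    clock_sd = max(_initial_value(pri.clock_sd), 1e-3)
    branch_rates = None
    if cfg.clock in ("UCLN", "UCED"):
        branch_rates = np.full(tree.n_nodes, clock_mean)
    pop_size = _initial_value(pri.pop_size)
    if cfg.estimate_ages and tree.root_age > 0:
        pop_size = max(pop_size, tree.root_age / 2.0)
    growth = _initial_value(pri.growth_rate) if cfg.demographic == "EGC" else 0.0
    base = cfg.substitution
    st = _State(
        parent=tree.parent.copy(),
        children=tree.children.copy(),
        postorder=tree.postorder.copy(),
        root=tree.root,
        age=tree.age.copy(),
        clock_mean=clock_mean,
        clock_sd=clock_sd,
        branch_rates=branch_rates,
        pop_size=pop_size,
        growth_rate=growth,
        freqs=base.base_freqs.copy(),
        exch=base.exchangeabilities.copy(),
        alpha=base.gamma_shape,
    )
    st.log_prior = ctx.log_prior(st)
    if not np.isfinite(st.log_prior):
        raise ValueError(
            "initial state has zero prior density; check tree ages against "
            "the model configuration"
        )
    st.log_lik = ctx.log_likelihood(st)
    return st


def _scalar_row(st: _State, ctx: _ModelContext, step: int, beta: float) -> dict:
    cfg = ctx.config
    row = {
        "step": step,
        "log_posterior": st.log_lik * beta + st.log_prior,
        "log_likelihood": st.log_lik,
        "log_prior": st.log_prior,
        "clock_mean": st.clock_mean,
        "pop_size": st.pop_size,
    }
    if cfg.estimate_ages:
        row["root_age"] = float(st.age[st.root])
    if cfg.clock == "UCLN":
        row["clock_sd"] = st.clock_sd
    if cfg.demographic == "EGC":
        row["growth_rate"] = st.growth_rate
    if cfg.estimate_substitution:
        for b, f in zip("ACGT", st.freqs):
            row[f"freq_{b}"] = f
        for nm, e in zip(_EXCH_NAMES, st.exch):
            row[f"exch_{nm}"] = e
        if st.alpha is not None:
            row["gamma_shape"] = st.alpha
    return row


def _run_chain(
    st: _State,
    ctx: _ModelContext,
    moves: list[tuple[_Move, float]],
    n_steps: int,
    sample_every: int,
    rng: np.random.Generator,
    beta: float,
    step_offset: int = 0,
):
    movelist = [m for m, _ in moves]
    n_acc = {m.name: 0 for m in movelist}
    n_try = {m.name: 0 for m in movelist}
    rows, ages, rates, parents = [], [], [], []
    if not movelist:  # fully pinned model: the chain is a point mass
        for step in range(sample_every, n_steps + 1, sample_every):
            rows.append(_scalar_row(st, ctx, step_offset + step, beta))
            ages.append(st.age.copy())
            rates.append(None if st.branch_rates is None else st.branch_rates.copy())
            parents.append(st.parent)
        return st, rows, ages, rates, parents, {}
    weights = np.array([w for _, w in moves])
    cum_w = np.cumsum(weights / weights.sum())
    for step in range(1, n_steps + 1):
        mi = int(np.searchsorted(cum_w, rng.random()))
        move = movelist[mi]
        n_try[move.name] += 1
        prop, log_h = move.propose(st, ctx, rng)
        if np.isfinite(log_h):
            lp = ctx.log_prior(prop)
            if np.isfinite(lp):
                prop.log_prior = lp
                prop.log_lik = ctx.log_likelihood(prop)
                log_ratio = (
                    beta * (prop.log_lik - st.log_lik)
                    + prop.log_prior
                    - st.log_prior
                    + log_h
                )
                if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
                    st = prop
                    n_acc[move.name] += 1
        if step % sample_every == 0:
            rows.append(_scalar_row(st, ctx, step_offset + step, beta))
            ages.append(st.age.copy())
            rates.append(
                None if st.branch_rates is None else st.branch_rates.copy()
            )
            parents.append(st.parent)
    acc = {
        name: (n_acc[name] / n_try[name]) if n_try[name] else 0.0
        for name in n_acc
    }
    return st, rows, ages, rates, parents, acc


def _upgma_starting_tree(alignment: Alignment, clock_rate: float) -> TimeTree:
    """UPGMA on JC distances, scaled to time by the initial clock rate."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    codes = alignment.codes
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4)
            if ok.sum() == 0:
                p = 0.0
            else:
                p = float(np.mean(codes[i][ok] != codes[j][ok]))
            p = min(p, 0.74)
            d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    z = hierarchy.linkage(squareform(d), method="average")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    eps = max(d.max(), 1e-3) * 1e-3
    for k, (a, b, height, _) in enumerate(z):
        node = n + k
        parent[int(a)] = node
        parent[int(b)] = node
        h = height / 2.0 / clock_rate
        age[node] = max(h, age[int(a)] + eps, age[int(b)] + eps)
    return TimeTree(alignment.taxa, parent, age, tip_dates=alignment.tip_dates)


def mcmc_run(
    alignment: Alignment,
    config: HierarchicalModelConfig,
    settings: MCMCSettings,
    tree: Optional[TimeTree] = None,
    beta: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> PosteriorTrace:
    """Run one Metropolis-Hastings chain and return the posterior trace.

    ``tree`` provides the starting (and, with ``topology_fixed``, the
    permanent) topology; if omitted a UPGMA tree built from JC distances
    is used.  ``beta`` tempers the likelihood (used by stepping-stone);
    the trace's ``log_posterior`` is ``beta * log_lik + log_prior``.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if tree is None:
        tree = _upgma_starting_tree(
            alignment, _initial_value(config.priors.clock_mean)
        )
    ctx = _ModelContext(alignment, config, tree)
    st = _initial_state(ctx, rng)
    moves = _build_moves(config)
    if not config.use_likelihood:
        beta = 0.0
    st, rows, ages, rates, parents, acc = _run_chain(
        st, ctx, moves, settings.chain_length, settings.sample_every, rng, beta
    )
    n_burn = int(round(settings.burnin_fraction * len(rows)))
    trace = PosteriorTrace(
        scalars=pd.DataFrame(rows[n_burn:]),
        ages=ages[n_burn:],
        branch_rates=rates[n_burn:],
        parents=parents[n_burn:],
        config=config,
        settings=settings,
        tip_names=tree.tip_names,
        acceptance=acc,
        _final_state=st,
        _ctx=ctx,
        _rng=rng,
    )
    trace.compute_ess()
    return trace


def extend_until_converged(
    trace: PosteriorTrace, settings: Optional[MCMCSettings] = None
) -> PosteriorTrace:
    """Double the chain until every parameter's ESS clears the threshold.

    Each doubling appends a continuation of the chain equal in length to
    everything run so far, with the sampling interval doubled (existing
    samples are thinned by two), so the retained sample count is
    approximately constant.  If ``max_doublings`` is exhausted with the
    minimum ESS still low, the trace is flagged, never silently passed.
    """
    settings = settings or trace.settings
    current_length = settings.chain_length
    sample_every = settings.sample_every
    while (
        trace.min_ess < settings.ess_threshold
        and trace.n_doublings < settings.max_doublings
    ):
        st = trace._final_state
        ctx = trace._ctx
        rng = trace._rng
        if st is None or ctx is None:
            trace.flags.append("cannot_extend")
            break
        sample_every *= 2
        beta = 1.0 if ctx.config.use_likelihood else 0.0
        st, rows, ages, rates, parents, acc = _run_chain(
            st,
            ctx,
            _build_moves(ctx.config),
            current_length,
            sample_every,
            rng,
            beta,
            step_offset=current_length,
        )
        current_length *= 2
        trace.scalars = pd.concat(
            [trace.scalars.iloc[1::2], pd.DataFrame(rows)], ignore_index=True
        )
        trace.ages = trace.ages[1::2] + ages
        trace.branch_rates = trace.branch_rates[1::2] + rates
        trace.parents = trace.parents[1::2] + parents
        trace._final_state = st
        trace.n_doublings += 1
        trace.compute_ess()
    if trace.min_ess < settings.ess_threshold:
        trace.flags.append("ess_below_threshold")
    return trace


# ---------------------------------------------------------------------------
# Stepping-stone marginal likelihood
# ---------------------------------------------------------------------------

@dataclass
class SteppingStoneResult:
    log_ml: float
    betas: np.ndarray
    per_stone: np.ndarray

    def __float__(self) -> float:
        return self.log_ml


def stepping_stone_logml(
    alignment: Alignment,
    config: HierarchicalModelConfig,
    settings: MCMCSettings,
    n_stones: int = 32,
    tree: Optional[TimeTree] = None,
    beta_shape: float = 0.3,
) -> SteppingStoneResult:
    """Stepping-stone estimate of the log marginal likelihood.

    Power posteriors are placed at β_k = (k/K)^(1/β_shape) (the
    quantiles of Beta(β_shape, 1)); each stone is sampled with the same
    kernel as :func:`mcmc_run`, chained from the previous stone's final
    state, with ``settings.chain_length`` steps per stone.  The
    estimator is Σ_k [logmeanexp_i (β_{k+1} - β_k) · loglik_i^{(k)}].
    """
    if n_stones < 1:
        raise ValueError("need at least one stone")
    if not config.priors.all_proper():
        raise ImproperPriorError(
            "stepping-stone sampling requires proper priors: every prior "
            "must integrate to 1, otherwise the marginal likelihood is "
            "undefined"
        )
    rng = np.random.default_rng(settings.seed)
    if tree is None:
        tree = _upgma_starting_tree(
            alignment, _initial_value(config.priors.clock_mean)
        )
    ctx = _ModelContext(alignment, config, tree)
    st = _initial_state(ctx, rng)
    moves = _build_moves(config)
    betas = (np.arange(n_stones + 1) / n_stones) ** (1.0 / beta_shape)
    contributions = np.empty(n_stones)
    for k in range(n_stones):
        st, rows, *_ = _run_chain(
            st,
            ctx,
            moves,
            settings.chain_length,
            settings.sample_every,
            rng,
            betas[k],
        )
        lls = np.array([r["log_likelihood"] for r in rows])
        n_burn = int(round(settings.burnin_fraction * len(lls)))
        lls = lls[n_burn:]
        d = betas[k + 1] - betas[k]
        contributions[k] = logsumexp(d * lls) - np.log(len(lls))
    return SteppingStoneResult(
        log_ml=float(contributions.sum()),
        betas=betas,
        per_stone=contributions,
    )


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class HierarchicalClockModel:
    """Bayesian hierarchical clock/demographic model bound to data.

    Parameters
    ----------
    alignment : training alignment (taxa must match ``tree`` when given).
    config : model combination (clock, demographic, substitution, priors).
    tree : starting topology/ages; required when ``config.topology_fixed``
        and no UPGMA start is wanted.
    """

    def __init__(
        self,
        alignment: Alignment,
        config: Optional[HierarchicalModelConfig] = None,
        tree: Optional[TimeTree] = None,
        **config_kwargs,
    ):
        if config is None:
            config = HierarchicalModelConfig(**config_kwargs)
        elif config_kwargs:
            config = replace(config, **config_kwargs)
        self.alignment = alignment
        self.config = config
        self.tree = tree

    @classmethod
    def from_files(
        cls,
        alignment_path: str,
        tree_path: Optional[str] = None,
        **kwargs,
    ) -> "HierarchicalClockModel":
        from .alignment import read_alignment
        from .trees import parse_newick

        aln = read_alignment(alignment_path)
        tree = None
        if tree_path is not None:
            with open(tree_path) as fh:
                tree = parse_newick(fh.read())
        return cls(aln, tree=tree, **kwargs)

    def fit(
        self,
        settings: Optional[MCMCSettings] = None,
        extend: bool = True,
    ) -> "ClockFitResults":
        settings = settings or MCMCSettings()
        trace = mcmc_run(self.alignment, self.config, settings, tree=self.tree)
        if extend:
            trace = extend_until_converged(trace, settings)
        return ClockFitResults(self, trace)

    def marginal_likelihood(
        self,
        settings: Optional[MCMCSettings] = None,
        n_stones: int = 32,
    ) -> SteppingStoneResult:
        settings = settings or MCMCSettings()
        return stepping_stone_logml(
            self.alignment, self.config, settings, n_stones=n_stones, tree=self.tree
        )

    @property
    def n_free_parameters(self) -> int:
        return n_free_parameters(self.config, self.alignment.n_taxa)


class ClockFitResults:
    """Posterior fit: trace, diagnostics, summaries and CV scoring."""

    def __init__(self, model: HierarchicalClockModel, trace: PosteriorTrace):
        self.model = model
        self.trace = trace

    @property
    def converged(self) -> bool:
        return "ess_below_threshold" not in self.trace.flags

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, equal-tailed 95% interval and ESS."""
        rows = []
        for col in self.trace.parameter_columns:
            vals = self.trace.scalars[col].to_numpy()
            rows.append(
                {
                    "parameter": col,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "2.5%": np.quantile(vals, 0.025),
                    "97.5%": np.quantile(vals, 0.975),
                    "ess": self.trace.ess.get(col, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def cv_score(self, test: Alignment, n_draws: int = 1000, seed: int = 0):
        from .model_selection import cv_score

        return cv_score(self.trace, test, n_draws, rng=np.random.default_rng(seed))

    def posterior_summary(self):
        from .model_selection import summarize_posterior

        return summarize_posterior(self.trace)

    def plot_trace(self, params: Optional[list[str]] = None, axes=None):
        """Trace plots of scalar parameters (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        params = params or self.trace.parameter_columns
        if axes is None:
            _, axes = plt.subplots(len(params), 1, figsize=(7, 2 * len(params)))
        if len(params) == 1:
            axes = [axes]
        for ax, col in zip(np.atleast_1d(axes), params):
            ax.plot(self.trace.scalars["step"], self.trace.scalars[col], lw=0.6)
            ax.set_ylabel(col)
        return axes
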