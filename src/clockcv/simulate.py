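"""Simulation of coalescent chronograms, clock rates and sequences.

This module reproduces the machinery of the validation study the
package is built around: Kingman-coalescent genealogies under constant
size (CSC) or exponential growth (EGC, population ``N(t) = N0 e^{-r t}``
backwards in time), branch substitution rates under strict (SC),
uncorrelated-lognormal (UCLN) or uncorrelated-exponential (UCED) clocks,
and Jukes-Cantor/GTR sequence evolution along the resulting phylogram.

Default study conditions: 50 contemporaneous taxa, root age rescaled to
100 years, mean rate 1e-3 subs/site/year (UCLN sd 10% of the mean; the
UCED's sd equals its mean by construction), EGC growth rate 0.25/year,
alignments of 5,000-15,000 nt under Jukes-Cantor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import SubstitutionModel, discrete_gamma_multipliers, transition_matrices
from .trees import BranchRateMap, SubstTree, TimeTree

__all__ = [
    "DemographicModel",
    "ClockModel",
    "SimulationConfig",
    "coalescent_intensity",
    "coalescent_intervals",
    "simulate_coalescent_tree",
    "rescale_root_age",
    "assign_branch_rates",
    "chronogram_to_phylogram",
    "simulate_alignment",
]


@dataclass(frozen=True)
class DemographicModel:
    """Coalescent demographic function N(t) = N0 e^{-r t} (t backwards).

    ``kind`` is "CSC" (r = 0) or "EGC"; the study's EGC growth rate is
    0.25 per year.  ``pop_size`` is N0 at sampling time.
    """

    kind: str = "CSC"
    pop_size: float = 1.0
    growth_rate: float = 0.0

    def __post_init__(self):
        if self.kind not in ("CSC", "EGC"):
            raise ValueError(f"unknown demographic model {self.kind!r}")
        if self.pop_size <= 0:
            raise ValueError("population size must be positive")
        if self.kind == "CSC" and self.growth_rate != 0.0:
            raise ValueError("CSC requires growth_rate = 0")


@dataclass(frozen=True)
class ClockModel:
    """Branch-rate process: SC, UCLN or UCED.

    ``mean_rate`` and ``rate_sd`` are real-space moments in
    subs/site/year.  SC forces sd 0; for UCED the exponential law pins
    sd = mean.
    """

    kind: str = "SC"
    mean_rate: float = 1e-3
    rate_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("SC", "UCLN", "UCED"):
            raise ValueError(f"unknown clock model {self.kind!r}")
        if self.mean_rate <= 0 or self.rate_sd < 0:
            raise ValueError("mean_rate must be > 0 and rate_sd >= 0")
        if self.kind == "SC" and self.rate_sd != 0.0:
            raise ValueError("SC clock has no rate spread")
        if self.kind == "UCED":
            object.__setattr__(self, "rate_sd", self.mean_rate)

    def lognormal_params(self) -> tuple[float, float]:
        """(M, S): log-space parameters matching real-space mean/sd."""
        s2 = np.log1p((self.rate_sd / self.mean_rate) ** 2)
        m = np.log(self.mean_rate) - s2 / 2.0
        return m, float(np.sqrt(s2))


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid."""

    n_taxa: int = 50
    root_age: float = 100.0
    seq_length: int = 5000
    n_replicates: int = 10
    clock: ClockModel = field(default_factory=ClockModel)
    demographic: DemographicModel = field(default_factory=DemographicModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2 or self.root_age <= 0 or self.seq_length < 1:
            raise ValueError("invalid simulation configuration")


def coalescent_intensity(t, demographic: DemographicModel):
    """Cumulative pairwise coalescent intensity Λ(t) = ∫0^t dt'/N(t')."""
    t = np.asarray(t, float)
    r, n0 = demographic.growth_rate, demographic.pop_size
    if r == 0.0:
        return t / n0
    return np.expm1(r * t) / (r * n0)


def coalescent_intervals(
    n_taxa: int,
    demographic: DemographicModel,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Inter-coalescent waiting times, shape (size, n_taxa-1).

    Column j is the waiting time while ``k = n_taxa - j`` lineages are
    active.  Times are obtained by inverting the cumulative coalescent
    intensity: with k lineages at time t0, the waiting time w satisfies
    [k(k-1)/2] * [Λ(t0+w) - Λ(t0)] = E, E ~ Exp(1); under CSC this is
    the familiar Exp(k(k-1)/(2 N0)) draw.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 lineages to coalesce")
    r, n0 = demographic.growth_rate, demographic.pop_size
    ks = np.arange(n_taxa, 1, -1)
    e = rng.exponential(size=(size, n_taxa - 1))
    if r == 0.0:
        return 2.0 * n0 * e / (ks * (ks - 1.0))[None, :]
    out = np.empty((size, n_taxa - 1))
    t0 = np.zeros(size)
    for j, k in enumerate(ks):
        pair = k * (k - 1.0) / 2.0
        w = np.log1p(r * n0 * e[:, j] / pair * np.exp(-r * t0)) / r
        out[:, j] = w
        t0 = t0 + w
    return out


def simulate_coalescent_tree(
    n_taxa: int,
    demographic: DemographicModel,
    rng: np.random.Generator,
) -> TimeTree:
    """Draw a Kingman-coalescent chronogram with contemporaneous tips."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    times = np.cumsum(coalescent_intervals(n_taxa, demographic, rng)[0])
    tip_names = [f"t{i + 1}" for i in range(n_taxa)]
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    active = list(range(n_taxa))
    for j, t in enumerate(times):
        node = n_taxa + j
        i1, i2 = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(i2)
        a = active.pop(i1)
        parent[a] = node
        parent[b] = node
        age[node] = t
        active.append(node)
    return TimeTree(tip_names, parent, age, tip_dates=np.zeros(n_taxa))


def rescale_root_age(tree: TimeTree, root_age: float) -> TimeTree:
    """Linearly rescale all node ages so the root sits at ``root_age``.

    Relative node ages are preserved exactly, which is the sense in
    which a coalescent-shaped genealogy keeps its demographic signature
    after conditioning the root.
    """
    current = tree.root_age
    if current <= 0:
        raise ValueError("cannot rescale a tree with zero root age")
    factor = root_age / current
    out = tree.copy()
    out.age = tree.age * factor
    out.age[tree.root] = root_age  # exact, no roundoff
    return out


def assign_branch_rates(
    tree: TimeTree, clock: ClockModel, rng: np.random.Generator
) -> BranchRateMap:
    """Draw per-branch rates under the configured clock.

    SC: all branches share ``mean_rate``.  UCLN: i.i.d. lognormal with
    real-space mean/sd moment-matched.  UCED: i.i.d. exponential with
    mean ``mean_rate``.
    """
    n = tree.n_nodes
    if clock.kind == "SC":
        rate = np.full(n, clock.mean_rate)
    elif clock.kind == "UCLN":
        m, s = clock.lognormal_params()
        rate = rng.lognormal(mean=m, sigma=s, size=n)
    else:  # UCED
        rate = rng.exponential(scale=clock.mean_rate, size=n)
    rate[tree.root] = clock.mean_rate  # root carries no branch
    return BranchRateMap(rate=rate, clock_kind=clock.kind)


def chronogram_to_phylogram(tree: TimeTree, rates: BranchRateMap) -> SubstTree:
    """Branch length = duration (years) x rate (subs/site/year)."""
    if rates.rate.shape != (tree.n_nodes,):
        raise ValueError(
            f"rate map covers {rates.rate.shape[0]} nodes, tree has {tree.n_nodes}"
        )
    return tree.to_subst_tree(rates)


def simulate_alignment(
    tree: SubstTree,
    model: SubstitutionModel,
    length: int,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve i.i.d. sites down the phylogram.

    Root states are drawn from the stationary frequencies and propagated
    through each branch's transition matrix; with +Γ configured, each
    site carries a category multiplier drawn uniformly over the discrete
    categories.
    """
    if length < 1:
        raise ValueError("alignment length must be at least 1")
    if model.gamma_shape is None:
        mults = np.ones(1)
        cats = np.zeros(length, dtype=np.int64)
    else:
        mults = discrete_gamma_multipliers(model.gamma_shape, model.n_categories)
        cats = rng.integers(len(mults), size=length)

    # per-category transition matrices for every branch
    pmats = np.stack(
        [transition_matrices(model, tree.branch_length * m) for m in mults]
    )  # (ncat, n_nodes, 4, 4)

    states = np.empty((tree.n_nodes, length), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=length, p=model.base_freqs)
    # preorder = reversed postorder, then tips
    order = list(tree.postorder[::-1])
    for node in order:
        for child in tree.children_of(node):
            probs = pmats[cats, child, states[node]]  # (length, 4)
            u = rng.random(length)
            drawn = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            states[child] = np.minimum(drawn, 3)
    codes = states[: tree.n_tips]
    return Alignment(tree.tip_names, codes, tip_dates=np.zeros(tree.n_tips))
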