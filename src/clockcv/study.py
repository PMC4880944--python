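"""Scaled-down replications of the simulation study's headline grids.

The full study design — 50-taxon chronograms with root age 100 years,
alignments of 5,000-15,000 nt, chains of 1e7 steps, ten replicates per
cell — needs cluster time.  The functions here run the same experiments
on a desk scale (fewer taxa, shorter alignments and chains) with the
generating parameters unchanged: mean rate 1e-3 subs/site/year, UCLN sd
10% of the mean, UCED sd equal to the mean, EGC growth rate 0.25/year,
Jukes-Cantor sequences.  Full-scale runs are a matter of passing
:class:`StudyScale` the original numbers.

Simulated tips are contemporaneous, so the data carry no calibration
signal for absolute rates; analyses therefore pin the clock's mean rate
to the generating value, the standard stand-in for date calibration,
and give the population size a diffuse lognormal prior centred on the
root-age scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import Alignment
from .likelihood import JC
from .mcmc import HierarchicalModelConfig, MCMCSettings, mcmc_run
from .model_selection import CVConfig, run_cross_validation, summarize_posterior
from .priors import LogNormalPrior, PointMassPrior, PriorSet
from .simulate import (
    ClockModel,
    DemographicModel,
    assign_branch_rates,
    chronogram_to_phylogram,
    rescale_root_age,
    simulate_alignment,
    simulate_coalescent_tree,
)
from .trees import TimeTree

__all__ = [
    "StudyScale",
    "DESK",
    "FULL",
    "simulate_dataset",
    "clock_selection_frequencies",
    "demographic_selection_frequencies",
    "growth_rate_coverage",
]

MEAN_RATE = 1e-3  # subs/site/year
GROWTH_RATE = 0.25  # per year, EGC simulations
ROOT_AGE = 100.0  # years
POP_SIZE = 50.0  # simulated N0 (the study never states its value)


@dataclass(frozen=True)
class StudyScale:
    """Problem sizes for one pass over a study grid."""

    n_taxa: int = 12
    seq_length: int = 1200
    n_replicates: int = 5
    chain_length: int = 12_000
    sample_every: int = 15
    n_posterior_draws: int = 300
    train_fraction: float = 0.5
    rescale_root: bool = True


DESK = StudyScale()
FULL = StudyScale(
    n_taxa=50,
    seq_length=10_000,
    n_replicates=10,
    chain_length=10_000_000,
    sample_every=5_000,
    n_posterior_draws=1_000,
)


def study_priors() -> PriorSet:
    """Analysis priors for the simulation experiments.

    The mean clock rate is pinned to the generating 1e-3 (the tips are
    contemporaneous, so absolute time is otherwise uncalibrated); N0
    gets a diffuse lognormal centred on the ~root-age scale.
    """
    return PriorSet(
        clock_mean=PointMassPrior(MEAN_RATE),
        pop_size=LogNormalPrior(mu=float(np.log(POP_SIZE)), sigma=2.0),
    )


def _clock_model(kind: str) -> ClockModel:
    sd = {"SC": 0.0, "UCLN": 0.1 * MEAN_RATE, "UCED": MEAN_RATE}[kind]
    return ClockModel(kind=kind, mean_rate=MEAN_RATE, rate_sd=sd)


def _demo_model(kind: str) -> DemographicModel:
    if kind == "CSC":
        return DemographicModel(kind="CSC", pop_size=POP_SIZE)
    return DemographicModel(kind="EGC", pop_size=POP_SIZE, growth_rate=GROWTH_RATE)


def simulate_dataset(
    clock_kind: str,
    demo_kind: str,
    scale: StudyScale,
    rng: np.random.Generator,
) -> tuple[TimeTree, Alignment]:
    """One replicate: chronogram, branch rates, JC alignment."""
    tree = simulate_coalescent_tree(scale.n_taxa, _demo_model(demo_kind), rng)
    if scale.rescale_root:
        tree = rescale_root_age(tree, ROOT_AGE)
    rates = assign_branch_rates(tree, _clock_model(clock_kind), rng)
    aln = simulate_alignment(
        chronogram_to_phylogram(tree, rates), JC(), scale.seq_length, rng
    )
    return tree, aln


def _settings(scale: StudyScale, seed: int) -> MCMCSettings:
    return MCMCSettings(
        chain_length=scale.chain_length,
        sample_every=scale.sample_every,
        burnin_fraction=0.10,
        ess_threshold=0,  # desk chains run at fixed length
        max_doublings=0,
        seed=seed,
    )


def _select_per_replicate(
    gen_clock: str,
    gen_demo: str,
    candidates: list[HierarchicalModelConfig],
    scale: StudyScale,
    seed: int,
) -> list[str]:
    """Simulate ``n_replicates`` datasets; CV-select a model for each."""
    master = np.random.SeedSequence(seed)
    winners = []
    for rep_ss in master.spawn(scale.n_replicates):
        sim_ss, cv_ss = rep_ss.spawn(2)
        tree, aln = simulate_dataset(
            gen_clock, gen_demo, scale, np.random.default_rng(sim_ss)
        )
        cv_seed = int(cv_ss.generate_state(1)[0] % (2**31))
        cv = CVConfig(
            train_fraction=scale.train_fraction,
            n_replicates=1,
            n_posterior_draws=scale.n_posterior_draws,
            models=candidates,
            seed=cv_seed,
        )
        result = run_cross_validation(
            aln, cv, _settings(scale, cv_seed), tree=tree
        )
        winners.append(result.selected_model)
    return winners


def clock_selection_frequencies(
    gen_clock: str,
    scale: StudyScale = DESK,
    seed: int = 0,
) -> dict[str, float]:
    """CV selection frequencies among SC/UCLN/UCED on one clock's data.

    Data are simulated under ``gen_clock`` with a constant-size
    coalescent; all three clock models (each with CSC) compete.
    """
    pri = study_priors()
    candidates = [
        HierarchicalModelConfig(clock=k, demographic="CSC", priors=pri)
        for k in ("SC", "UCLN", "UCED")
    ]
    winners = _select_per_replicate(gen_clock, "CSC", candidates, scale, seed)
    return {
        f"{k}+CSC": winners.count(f"{k}+CSC") / len(winners)
        for k in ("SC", "UCLN", "UCED")
    }


def demographic_selection_frequencies(
    gen_demo: str,
    scale: StudyScale = DESK,
    seed: int = 0,
) -> dict[str, float]:
    """CV selection frequencies between CSC and EGC tree priors.

    Data are simulated under ``gen_demo`` with a strict clock; SC+CSC
    and SC+EGC compete.
    """
    pri = study_priors()
    candidates = [
        HierarchicalModelConfig(clock="SC", demographic=d, priors=pri)
        for d in ("CSC", "EGC")
    ]
    winners = _select_per_replicate("SC", gen_demo, candidates, scale, seed)
    return {
        f"SC+{d}": winners.count(f"SC+{d}") / len(winners)
        for d in ("CSC", "EGC")
    }


def growth_rate_coverage(
    n_replicates: int = 20,
    scale: StudyScale = DESK,
    seed: int = 0,
) -> float:
    """Fraction of replicates whose 95% CrI covers the true growth rate.

    Data are simulated under (SC, EGC r=0.25) *without* root-age
    rescaling (rescaling would change the realised growth rate), then
    analysed under the matching SC+EGC model.
    """
    sim_scale = replace(scale, rescale_root=False, n_replicates=n_replicates)
    cfg = HierarchicalModelConfig(
        clock="SC", demographic="EGC", priors=study_priors()
    )
    master = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in master.spawn(n_replicates):
        sim_ss, chain_ss = rep_ss.spawn(2)
        tree, aln = simulate_dataset(
            "SC", "EGC", sim_scale, np.random.default_rng(sim_ss)
        )
        chain_seed = int(chain_ss.generate_state(1)[0] % (2**31))
        trace = mcmc_run(
            aln, cfg, _settings(scale, chain_seed), tree=tree,
            rng=np.random.default_rng(chain_ss),
        )
        lo, hi = summarize_posterior(trace).growth_rate_interval
        hits += int(lo <= GROWTH_RATE <= hi)
    return hits / n_replicates
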