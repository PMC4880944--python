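"""Site-wise cross-validation model selection and posterior summaries.

The procedure: split alignment sites at random into disjoint training
and test sets (50/50 or 80/20), fit each candidate hierarchical model
to the training set by MCMC, then score each model by the mean over
posterior draws of the test-set log-likelihood — each draw's chronogram
is converted to a phylogram (branch duration x branch rate) and the
test sites are evaluated under that draw's substitution parameters.
The model with the highest mean test score across replicates wins;
ties go to the model with fewer free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .alignment import Alignment, SiteSplit
from .likelihood import tree_log_likelihood
from .mcmc import (
    HierarchicalModelConfig,
    MCMCSettings,
    PosteriorTrace,
    extend_until_converged,
    mcmc_run,
    n_free_parameters,
)
from .trees import TimeTree

__all__ = [
    "CVConfig",
    "CVScore",
    "CVResult",
    "PosteriorSummary",
    "split_sites",
    "cv_score",
    "run_cross_validation",
    "summarize_posterior",
    "select_best",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings (defaults match the study design)."""

    train_fraction: float = 0.5
    n_replicates: int = 10
    n_posterior_draws: int = 1000
    models: Sequence[HierarchicalModelConfig] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1 or self.n_posterior_draws < 1:
            raise ValueError("need at least one replicate and one draw")


def split_sites(
    alignment: Alignment,
    train_fraction: float,
    rng: np.random.Generator,
) -> SiteSplit:
    """Random disjoint train/test partition of the alignment's sites."""
    n = alignment.n_sites
    if n < 2:
        raise ValueError("alignment must have at least 2 sites to split")
    n_train = round(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train fraction {train_fraction} leaves an empty partition "
            f"for {n} sites"
        )
    perm = rng.permutation(n)
    return SiteSplit(
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
        train_fraction=train_fraction,
    )


@dataclass(frozen=True)
class CVScore:
    """Test-set predictive score from one fitted model.

    ``mean_log`` is the primary score (arithmetic mean over posterior
    draws of the test-set log-likelihood); ``log_mean_exp`` is the
    log-of-mean-likelihood diagnostic; ``resampled`` flags traces with
    fewer retained samples than requested draws.
    """

    mean_log: float
    log_mean_exp: float
    n_draws: int
    resampled: bool = False


def cv_score(
    trace: PosteriorTrace,
    test: Alignment,
    n_draws: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> CVScore:
    """Score a posterior trace against held-out sites.

    For each drawn posterior sample the chronogram and branch rates are
    multiplied into a phylogram and the test alignment's log-likelihood
    is evaluated under the sample's substitution parameters.
    """
    if len(trace) == 0:
        raise ValueError("posterior trace is empty")
    if set(trace.tip_names) != set(test.taxa):
        raise ValueError(
            "taxa differ between trace and test alignment: "
            f"{sorted(set(trace.tip_names) ^ set(test.taxa))}"
        )
    rng = rng or np.random.default_rng(0)
    n = len(trace)
    resampled = n < n_draws
    if resampled:
        idx = rng.integers(n, size=n_draws)
    else:
        idx = rng.choice(n, size=n_draws, replace=False)
    lls = np.empty(n_draws)
    for j, i in enumerate(idx):
        i = int(i)
        tree = trace.sample_tree(i)
        rates = trace.sample_rates(i)
        phylo = tree.to_subst_tree(rates)
        model = trace.sample_subst_model(i)
        lls[j] = tree_log_likelihood(phylo, test, model)
    return CVScore(
        mean_log=float(lls.mean()),
        log_mean_exp=float(logsumexp(lls) - np.log(n_draws)),
        n_draws=n_draws,
        resampled=resampled,
    )


def select_best(
    grand_means: Mapping[str, float],
    param_counts: Optional[Mapping[str, int]] = None,
) -> str:
    """Argmax model label; ties broken by fewest free parameters."""
    best = max(grand_means.values())
    tied = [m for m, v in grand_means.items() if v == best]
    if len(tied) > 1 and param_counts is not None:
        tied.sort(key=lambda m: (param_counts.get(m, np.inf), m))
    return tied[0]


@dataclass
class CVResult:
    """Replicate-level CV scores and the selected model.

    ``scores`` is (model x replicate) mean test log-likelihoods;
    ``grand_mean``/``standard_error`` aggregate across replicates (SE =
    sample sd / sqrt(n)); ``selected_model`` attains the maximum grand
    mean.
    """

    scores: pd.DataFrame
    grand_mean: pd.Series
    standard_error: pd.Series
    selected_model: str
    log_mean_exp: Optional[pd.DataFrame] = None
    failures: list[tuple[str, int, str]] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.grand_mean, "se": self.standard_error}
        ).sort_values("mean", ascending=False)


def run_cross_validation(
    alignment: Alignment,
    cv: CVConfig,
    mcmc: MCMCSettings,
    tree: Optional[TimeTree] = None,
) -> CVResult:
    """Repeated random-split cross-validation over candidate models.

    One site split is drawn per replicate and shared by every model, so
    between-model contrasts are paired.  Each model is fitted to the
    training sites with the ESS doubling rule, then scored on the test
    sites.  A failed chain flags and excludes that (model, replicate)
    cell rather than aborting the run.
    """
    if not cv.models:
        raise ValueError("configure at least one model to compare")
    labels = [m.label for m in cv.models]
    if len(set(labels)) != len(labels):
        raise ValueError("model labels must be unique")
    master = np.random.SeedSequence(cv.seed)
    rep_seeds = master.spawn(cv.n_replicates)
    scores = pd.DataFrame(index=labels, columns=range(cv.n_replicates), dtype=float)
    lme = scores.copy()
    failures: list[tuple[str, int, str]] = []
    seeds_log: dict = {"master_seed": cv.seed}
    for rep in range(cv.n_replicates):
        split_seed, chain_seed, draw_seed = rep_seeds[rep].spawn(3)
        split_rng = np.random.default_rng(split_seed)
        split = split_sites(alignment, cv.train_fraction, split_rng)
        train = alignment.take_sites(split.train_indices)
        test = alignment.take_sites(split.test_indices)
        seeds_log[f"replicate_{rep}"] = {
            "entropy": int(rep_seeds[rep].entropy) % (2**63),
        }
        for m_i, model_cfg in enumerate(cv.models):
            label = labels[m_i]
            try:
                chain_rng = np.random.default_rng(
                    chain_seed.spawn(len(cv.models))[m_i]
                )
                trace = mcmc_run(
                    train, model_cfg, mcmc, tree=tree, rng=chain_rng
                )
                trace = extend_until_converged(trace, mcmc)
                sc = cv_score(
                    trace,
                    test,
                    cv.n_posterior_draws,
                    rng=np.random.default_rng(draw_seed.spawn(len(cv.models))[m_i]),
                )
            except Exception as exc:  # failed chain: flag and exclude
                failures.append((label, rep, str(exc)))
                continue
            scores.loc[label, rep] = sc.mean_log
            lme.loc[label, rep] = sc.log_mean_exp
    grand = scores.mean(axis=1, skipna=True)
    n_ok = scores.notna().sum(axis=1)
    se = scores.std(axis=1, ddof=1, skipna=True) / np.sqrt(n_ok)
    counts = {
        lab: n_free_parameters(m, alignment.n_taxa)
        for lab, m in zip(labels, cv.models)
    }
    selected = select_best(grand.to_dict(), counts)
    return CVResult(
        scores=scores,
        grand_mean=grand,
        standard_error=se,
        selected_model=selected,
        log_mean_exp=lme,
        failures=failures,
        seeds=seeds_log,
    )


@dataclass
class PosteriorSummary:
    """Clock-likeness and demographic-growth posterior summaries.

    ``rate_cv`` is the per-sample coefficient of variation of branch
    rates (sample sd / mean); ``growth_rate_interval`` is the
    equal-tailed 95% credible interval of the growth rate.  The flags
    interpret them: a rate-CV posterior piled up near zero means
    clock-like evolution; a growth interval containing zero means the
    data are compatible with a constant population size.
    """

    rate_cv: Optional[np.ndarray] = None
    growth_rate_interval: Optional[tuple[float, float]] = None
    clock_like: Optional[bool] = None
    constant_size: Optional[bool] = None


def summarize_posterior(trace: PosteriorTrace) -> PosteriorSummary:
    """Fig.-1-style posterior summaries from a fitted trace."""
    out = PosteriorSummary()
    if trace.config.clock == "SC":
        # one shared rate: the coefficient of variation is identically 0
        out.rate_cv = np.zeros(len(trace))
    else:
        cvs = np.empty(len(trace))
        for i in range(len(trace)):
            r = trace.sample_rates(i).rate
            r = np.delete(r, np.argmax(trace.ages[i]))  # drop root slot
            m = r.mean()
            sd = r.std(ddof=1) if len(r) > 1 else 0.0
            cvs[i] = sd / m if m > 0 else 0.0
        out.rate_cv = cvs
    # clock-like when the posterior mass concentrates near zero
    out.clock_like = bool(np.median(out.rate_cv) < 0.1)
    if trace.config.demographic == "EGC":
        g = trace.scalars["growth_rate"].to_numpy()
        lo, hi = np.quantile(g, [0.025, 0.975])
        out.growth_rate_interval = (float(lo), float(hi))
        out.constant_size = bool(lo <= 0.0 <= hi)
    elif trace.config.demographic == "CSC":
        pass
    return out
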