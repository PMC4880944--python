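"""Coalescent/clock densities, MCMC machinery, ESS and stepping-stone."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp

import clockcv as cc
from clockcv.mcmc import (
    EssValue,
    GrowthWalk,
    HierarchicalModelConfig,
    ImproperPriorError,
    MCMCSettings,
    ScalarMultiplier,
    _clock_log_density_arrays,
    clock_log_density,
    coalescent_log_density,
    effective_sample_size,
    extend_until_converged,
    mcmc_run,
    stepping_stone_logml,
)
from clockcv.priors import (
    ImproperUniformPrior,
    LogNormalPrior,
    PointMassPrior,
    PriorSet,
)
from clockcv.simulate import ClockModel, DemographicModel
from clockcv.trees import BranchRateMap, TimeTree


@pytest.fixture
def fixed_pair():
    return TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 0.5])


class TestCoalescentDensity:
    def test_two_tip_closed_form(self, fixed_pair):
        """Exp(1) waiting time: log density at t=0.5 is -0.5."""
        demo = DemographicModel(kind="CSC", pop_size=1.0)
        assert coalescent_log_density(fixed_pair, demo) == pytest.approx(-0.5)

    def test_egc_zero_growth_equals_csc(self, rng):
        tree = cc.simulate_coalescent_tree(
            9, DemographicModel(kind="CSC", pop_size=4.0), rng
        )
        csc = coalescent_log_density(tree, DemographicModel("CSC", 3.0))
        egc = coalescent_log_density(
            tree, DemographicModel("EGC", 3.0, growth_rate=0.0)
        )
        assert egc == pytest.approx(csc, abs=1e-10)

    def test_density_decreases_for_large_popsize(self, fixed_pair):
        """Short coalescent times become improbable as N0 grows."""
        vals = [
            coalescent_log_density(fixed_pair, DemographicModel("CSC", n0))
            for n0 in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_serial_sampling_two_intervals(self):
        """Heterochronous tips change the lineage count trajectory."""
        # B sampled 1 year before A; coalescence at 2: single lineage
        # on [1,2]... wait, A at 0, B at 1, coalescence at 2.
        tree = TimeTree(["A", "B"], [2, 2, -1], [0.0, 1.0, 2.0])
        demo = DemographicModel("CSC", pop_size=1.0)
        # k=1 on [0,1] contributes 0; k=2 on [1,2] contributes -1
        assert coalescent_log_density(tree, demo) == pytest.approx(-1.0)

    def test_integrates_to_one_two_tips(self):
        """The 2-tip EGC density is a proper density over the age."""
        demo = DemographicModel("EGC", pop_size=2.0, growth_rate=0.5)
        def dens(t):
            tree = TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, t])
            return np.exp(coalescent_log_density(tree, demo))
        val, _ = integrate.quad(dens, 0, 50, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestClockDensity:
    def test_sc_density_is_zero(self):
        rates = BranchRateMap(np.full(5, 1e-3), "SC")
        assert clock_log_density(rates, ClockModel(kind="SC")) == 0.0

    def test_uced_unit_mean_closed_form(self):
        rates = BranchRateMap(np.array([1.0]), "UCED")
        clock = ClockModel(kind="UCED", mean_rate=1.0)
        assert clock_log_density(rates, clock) == pytest.approx(-1.0)

    def test_ucln_density_normalised(self):
        """UCLN branch-rate density integrates to 1 (quadrature)."""
        clock = ClockModel(kind="UCLN", mean_rate=1.0, rate_sd=0.5)
        _, s = clock.lognormal_params()
        val, _ = integrate.quad(
            lambda x: np.exp(
                _clock_log_density_arrays(np.array([x]), "UCLN", 1.0, s)
            ),
            1e-9,
            60.0,
            limit=300,
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            _clock_log_density_arrays(np.array([-1.0]), "UCED", 1.0, 0.0)


class TestEffectiveSampleSize:
    def test_white_noise_ess_near_n(self, rng):
        x = rng.normal(size=1_000)
        assert 800 <= effective_sample_size(x) <= 1_200

    def test_ar1_ess_matches_closed_form(self, rng):
        """AR(1) with φ=0.9: ESS ≈ n (1-φ)/(1+φ)."""
        phi, n = 0.9, 10_000
        eps = rng.normal(size=n) * np.sqrt(1 - phi**2)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        want = n * (1 - phi) / (1 + phi)
        got = effective_sample_size(x)
        assert abs(got - want) / want < 0.30

    def test_constant_series_flagged(self):
        e = effective_sample_size(np.full(50, 3.14))
        assert e == 1.0 and e.degenerate

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5))


class TestDetailedBalance:
    """Proposal-density bookkeeping: the returned Hastings term must
    equal log q(x|x') - log q(x'|x) for every reversible scalar move."""

    @pytest.mark.parametrize("x", [0.01, 1.0, 37.5])
    def test_multiplier_move(self, x, rng):
        move = ScalarMultiplier("m", "pop_size")
        for _ in range(20):
            class S:  # tiny stand-in state
                pop_size = x
                def copy(self):
                    s = S(); s.pop_size = self.pop_size; return s
            st = S()
            new, log_h = move.propose(st, None, rng)
            y = new.pop_size
            want = move.log_proposal_density(y, x) - move.log_proposal_density(x, y)
            assert log_h == pytest.approx(want, abs=1e-10)

    def test_random_walk_move_symmetric(self, rng):
        move = GrowthWalk()
        class S:
            growth_rate = 0.3
            def copy(self):
                s = S(); s.growth_rate = self.growth_rate; return s
        st = S()
        new, log_h = move.propose(st, None, rng)
        y = new.growth_rate
        assert log_h == 0.0
        assert move.log_proposal_density(0.3, y) == pytest.approx(
            move.log_proposal_density(y, 0.3), abs=1e-12
        )


def _prior_chain(config, tree, aln, seed, chain_length=30_000, every=15):
    settings = MCMCSettings(
        chain_length=chain_length,
        sample_every=every,
        ess_threshold=0,
        max_doublings=0,
        seed=seed,
    )
    return mcmc_run(aln, config, settings, tree=tree)


class TestPriorSampling:
    """With the likelihood disabled, marginals must match their priors."""

    @pytest.fixture
    def prior_setup(self, rng):
        demo = DemographicModel("CSC", pop_size=10.0)
        tree = cc.simulate_coalescent_tree(6, demo, rng)
        rates = cc.assign_branch_rates(tree, ClockModel("SC"), rng)
        aln = cc.simulate_alignment(tree.to_subst_tree(rates), cc.JC(), 50, rng)
        return tree, aln

    @staticmethod
    def _direct_growth_sample(n_tips, n0_prior, rng, size):
        """Rejection-sample the joint (growth rate, genealogy) prior.

        For r < 0 the exponential-decline coalescent is defective (the
        cumulative intensity is bounded, so lineages may never
        coalesce); draws whose genealogies fail to coalesce are
        rejected, which tilts the growth-rate marginal positive exactly
        as the joint model does.
        """
        out = []
        while len(out) < size:
            r = rng.laplace(0.0, 1.0)
            n0 = n0_prior.sample(rng)
            t0, ok = 0.0, True
            for k in range(n_tips, 1, -1):
                pair = k * (k - 1) / 2.0
                e = rng.exponential()
                if r == 0.0:
                    w = n0 * e / pair
                else:
                    arg = 1.0 + r * n0 * e / pair * np.exp(-r * t0)
                    if arg <= 0:
                        ok = False
                        break
                    w = np.log(arg) / r
                t0 += w
            if ok:
                out.append(r)
        return np.array(out)

    def test_growth_rate_matches_joint_prior(self, prior_setup, rng):
        """Prior-only growth marginal equals the rejection-sampled one."""
        tree, aln = prior_setup
        from clockcv.priors import LogNormalPrior

        n0_prior = LogNormalPrior(mu=0.0, sigma=2.0)
        cfg = HierarchicalModelConfig(
            clock="SC",
            demographic="EGC",
            use_likelihood=False,
            priors=PriorSet(pop_size=n0_prior),
        )
        trace = _prior_chain(cfg, tree, aln, seed=81, chain_length=120_000)
        g = trace.scalars["growth_rate"].to_numpy()[::20]
        direct = self._direct_growth_sample(6, n0_prior, rng, 4_000)
        assert stats.ks_2samp(g, direct).pvalue > 0.01

    def test_root_age_matches_direct_coalescent_simulation(self, prior_setup, rng):
        tree, aln = prior_setup
        n0 = 10.0
        cfg = HierarchicalModelConfig(
            clock="SC",
            demographic="CSC",
            use_likelihood=False,
            priors=PriorSet(pop_size=PointMassPrior(n0)),
        )
        trace = _prior_chain(cfg, tree, aln, seed=82, chain_length=60_000)
        sampled = trace.scalars["root_age"].to_numpy()[::10]
        demo = DemographicModel("CSC", pop_size=n0)
        direct = cc.simulate.coalescent_intervals(
            6, demo, rng, size=4_000
        ).sum(axis=1)
        assert stats.ks_2samp(sampled, direct).pvalue > 0.01

    def test_clock_sd_matches_exponential_prior(self, prior_setup):
        tree, aln = prior_setup
        cfg = HierarchicalModelConfig(
            clock="UCLN", demographic="CSC", use_likelihood=False
        )
        trace = _prior_chain(cfg, tree, aln, seed=83, chain_length=150_000)
        s = trace.scalars["clock_sd"].to_numpy()[::20]
        assert stats.kstest(s, stats.expon(scale=0.3).cdf).pvalue > 0.01


class TestMCMCBookkeeping:
    def test_log_posterior_identity(self, simulated_sc_data):
        tree, rates, aln = simulated_sc_data
        cfg = HierarchicalModelConfig(clock="SC", demographic="CSC")
        settings = MCMCSettings(
            chain_length=2_000, sample_every=20, ess_threshold=0,
            max_doublings=0, seed=5,
        )
        trace = mcmc_run(aln, cfg, settings, tree=tree)
        np.testing.assert_allclose(
            trace.scalars["log_posterior"],
            trace.scalars["log_likelihood"] + trace.scalars["log_prior"],
            atol=1e-8,
        )

    def test_retained_samples_satisfy_tree_invariants(self, simulated_sc_data):
        tree, rates, aln = simulated_sc_data
        cfg = HierarchicalModelConfig(clock="UCED", demographic="CSC")
        settings = MCMCSettings(
            chain_length=2_000, sample_every=40, ess_threshold=0,
            max_doublings=0, seed=6,
        )
        trace = mcmc_run(aln, cfg, settings, tree=tree)
        for i in range(len(trace)):
            t = trace.sample_tree(i)  # constructor re-validates
            r = trace.sample_rates(i)
            assert np.all(np.delete(r.rate, t.root) > 0)

    def test_two_taxon_rate_recovery(self, rng):
        """Fixed tree, long SC alignment: posterior mean rate within 5%."""
        tree = TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 50.0])
        rates = BranchRateMap(np.full(3, 1e-3), "SC")
        aln = cc.simulate_alignment(tree.to_subst_tree(rates), cc.JC(), 20_000, rng)
        cfg = HierarchicalModelConfig(
            clock="SC",
            demographic="CSC",
            estimate_ages=False,
            priors=PriorSet(pop_size=PointMassPrior(25.0)),
        )
        settings = MCMCSettings(
            chain_length=20_000, sample_every=10, ess_threshold=100,
            max_doublings=1, seed=7,
        )
        trace = mcmc_run(aln, cfg, settings, tree=tree)
        post_mean = trace.scalars["clock_mean"].mean()
        assert post_mean == pytest.approx(1e-3, rel=0.05)


class TestExtension:
    def _quick_trace(self, simulated_sc_data, threshold, max_doublings):
        tree, rates, aln = simulated_sc_data
        cfg = HierarchicalModelConfig(clock="SC", demographic="CSC")
        settings = MCMCSettings(
            chain_length=1_000, sample_every=10,
            ess_threshold=threshold, max_doublings=max_doublings, seed=9,
        )
        return mcmc_run(aln, cfg, settings, tree=tree), settings

    def test_no_extension_above_threshold(self, simulated_sc_data):
        trace, settings = self._quick_trace(simulated_sc_data, 0, 2)
        out = extend_until_converged(trace, settings)
        assert out.n_doublings == 0 and not out.flags

    def test_doubling_preserves_sample_count(self, simulated_sc_data):
        trace, settings = self._quick_trace(simulated_sc_data, 1e9, 1)
        n_before = len(trace)
        out = extend_until_converged(trace, settings)
        assert out.n_doublings == 1
        # thinned old half + fresh half: count stays approximately flat
        # (exact equality is broken only by the initial burn-in removal)
        assert abs(len(out) - n_before) <= 0.15 * n_before

    def test_capped_chain_is_flagged(self, simulated_sc_data):
        trace, settings = self._quick_trace(simulated_sc_data, 1e9, 0)
        out = extend_until_converged(trace, settings)
        assert out.n_doublings == 0
        assert "ess_below_threshold" in out.flags


@pytest.fixture(scope="module")
def quadrature_problem():
    """2-taxon fixed tree, single free rate with a lognormal prior."""
    rng = np.random.default_rng(99)
    tree = TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 50.0])
    rates = BranchRateMap(np.full(3, 1e-3), "SC")
    aln = cc.simulate_alignment(tree.to_subst_tree(rates), cc.JC(), 400, rng)
    prior = LogNormalPrior(mu=float(np.log(1e-3)), sigma=0.5)
    cfg = HierarchicalModelConfig(
        clock="SC",
        demographic="CSC",
        estimate_ages=False,
        priors=PriorSet(clock_mean=prior, pop_size=PointMassPrior(10.0)),
    )
    # 1-D quadrature over log rate
    grid = np.linspace(np.log(1e-3) - 3.5, np.log(1e-3) + 3.5, 600)
    vals = np.empty_like(grid)
    for i, lr in enumerate(grid):
        r = np.exp(lr)
        ll = cc.tree_log_likelihood(
            tree.to_subst_tree(BranchRateMap(np.full(3, r), "SC")), aln, cc.JC()
        )
        vals[i] = ll + prior.log_pdf(r) + lr  # Jacobian of log transform
    log_quad = logsumexp(vals) + np.log(grid[1] - grid[0])
    return tree, aln, cfg, float(log_quad)


class TestSteppingStone:
    def _point_mass_config(self):
        return HierarchicalModelConfig(
            clock="SC",
            demographic="CSC",
            estimate_ages=False,
            priors=PriorSet(
                clock_mean=PointMassPrior(1e-3),
                pop_size=PointMassPrior(10.0),
            ),
        )

    def test_point_mass_prior_recovers_log_likelihood(self, rng):
        """With all parameters pinned, logML is the plug-in likelihood."""
        tree = TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 50.0])
        rates = BranchRateMap(np.full(3, 1e-3), "SC")
        aln = cc.simulate_alignment(tree.to_subst_tree(rates), cc.JC(), 300, rng)
        cfg = self._point_mass_config()
        settings = MCMCSettings(
            chain_length=200, sample_every=10, ess_threshold=0,
            max_doublings=0, seed=13,
        )
        res = stepping_stone_logml(aln, cfg, settings, n_stones=4, tree=tree)
        want = cc.tree_log_likelihood(
            tree.to_subst_tree(rates), aln, cc.JC()
        )
        assert res.log_ml == pytest.approx(want, abs=1e-6)

    def test_improper_prior_refused(self, rng):
        tree = TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 50.0])
        rates = BranchRateMap(np.full(3, 1e-3), "SC")
        aln = cc.simulate_alignment(tree.to_subst_tree(rates), cc.JC(), 50, rng)
        cfg = HierarchicalModelConfig(
            clock="SC",
            demographic="CSC",
            priors=PriorSet(growth_rate=ImproperUniformPrior()),
        )
        with pytest.raises(ImproperPriorError, match="proper"):
            stepping_stone_logml(
                aln, cfg, MCMCSettings(chain_length=100, sample_every=10, seed=1),
                n_stones=2, tree=tree,
            )

    def _run_ss(self, quadrature_problem, n_stones, seed=11):
        tree, aln, cfg, _ = quadrature_problem
        settings = MCMCSettings(
            chain_length=3_000, sample_every=10, ess_threshold=0,
            max_doublings=0, seed=seed,
        )
        return stepping_stone_logml(aln, cfg, settings, n_stones=n_stones, tree=tree)

    def test_matches_quadrature_within_half_log_unit(self, quadrature_problem):
        res = self._run_ss(quadrature_problem, n_stones=16)
        assert abs(res.log_ml - quadrature_problem[3]) < 0.5

    def test_more_stones_reduce_discretisation_error(self, quadrature_problem):
        """Error shrinks from a deliberately coarse ladder to a fine one."""
        errs = [
            abs(self._run_ss(quadrature_problem, K).log_ml - quadrature_problem[3])
            for K in (1, 8, 64)
        ]
        assert errs[2] < errs[0]
        assert errs[1] < errs[0]

    def test_deterministic_given_seed(self, quadrature_problem):
        a = self._run_ss(quadrature_problem, 4, seed=21)
        b = self._run_ss(quadrature_problem, 4, seed=21)
        assert a.log_ml == b.log_ml
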