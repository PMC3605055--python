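import math
import random

import numpy as np
import pytest

from conftest import T1_P, small_generated_params, toy_config
from parsnet import (
    ChainConfig,
    DegenerateSamplingSpaceError,
    acceptance_probability,
    batch_autocorrelation,
    effective_sample_size,
    ergodic_average_trace,
    estimate_marginals,
    exact_marginals,
    forced_reactions,
    generate_network,
    max_likelihood_subnetwork,
    propose,
    run_chain,
    uncorrected_chain_stationary_marginals,
    valid_neighbors,
)
from parsnet.sampler import HASTINGS_CORRECTED, MarginalProfile, SampleSet


class TestPropose:
    def test_t1_toggles_enumerated(self, t1):
        full = t1.full_subnetwork()
        neigh = {frozenset(n.included_reactions) for n in valid_neighbors(full)}
        assert neigh == {frozenset({"r1"}), frozenset({"r2"})}
        cand, delta, n_invalid = propose(full, random.Random(0))
        assert cand.included_reactions in ({"r1"}, {"r2"})
        assert delta == -1
        assert n_invalid == 0

    def test_invalid_toggle_redrawn(self, t1):
        rng = random.Random(3)
        seen_invalid = 0
        for _ in range(50):
            cand, delta, n_invalid = propose(t1.subnetwork({"r1"}), rng)
            assert cand.included_reactions == {"r1", "r2"}  # only valid move
            assert delta == 1
            seen_invalid += n_invalid
        assert seen_invalid > 0  # deleting r1 must sometimes have been drawn

    def test_degenerate_space_raises(self, mono_only):
        with pytest.raises(DegenerateSamplingSpaceError):
            propose(mono_only.full_subnetwork(), random.Random(0))
        with pytest.raises(DegenerateSamplingSpaceError):
            run_chain(mono_only, toy_config())


class TestAcceptanceProbability:
    @pytest.mark.parametrize(
        "delta, lam, expected",
        [(-1, 1.0, 1.0), (0, 1.0, 1.0), (2, 1.0, math.exp(-2)), (1, 0.5, math.exp(-0.5))],
    )
    def test_paper_faithful_form(self, delta, lam, expected):
        assert acceptance_probability(delta, lam) == pytest.approx(expected)

    def test_hastings_asymmetry_ratio(self):
        assert acceptance_probability(
            1, 1.0, HASTINGS_CORRECTED, asymmetry_ratio=0.5
        ) == pytest.approx(0.5 * math.exp(-1))
        assert acceptance_probability(
            -2, 1.0, HASTINGS_CORRECTED, asymmetry_ratio=0.1
        ) == pytest.approx(min(1.0, math.exp(2) * 0.1))


class TestRunChain:
    def test_seeded_determinism_bit_identical(self, t1):
        cfg = toy_config(seed=7, n_samples=2_000)
        a = run_chain(t1, cfg)
        b = run_chain(t1, cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate
        assert a.min_subnetwork.included_reactions == b.min_subnetwork.included_reactions

    def test_every_stored_sample_is_valid(self, shared_chain):
        ss = run_chain(shared_chain, toy_config(seed=5, n_samples=3_000))
        rids = ss.reaction_ids
        for row in ss.samples[::101]:
            chosen = {r for r, b in zip(rids, row) if b}
            assert shared_chain.subnetwork(chosen).is_valid()

    def test_forced_reaction_always_included(self, forced_net):
        ss = run_chain(forced_net, toy_config(seed=2, n_samples=5_000))
        prof = estimate_marginals(ss)
        assert prof["r2"] == 1.0

    def test_lambda_zero_accepts_every_valid_proposal(self, t1):
        ss = run_chain(t1, toy_config(seed=9, lam=0.0, n_samples=2_000))
        assert ss.acceptance_rate == 1.0

    def test_t1_converges_to_uncorrected_stationary_law(self, t1):
        # T1 is the regression fixture where the retry-until-valid proposal
        # asymmetry is largest: the uncorrected chain's own stationary law
        # (P(r1)=0.6345) differs from pi ∝ exp(-lam*|C|) by 0.057.  The
        # sampler must match the former exactly, not drift anywhere else.
        expected = uncorrected_chain_stationary_marginals(t1, lam=1.0)
        ss = run_chain(t1, toy_config(seed=11))
        prof = estimate_marginals(ss)
        for rid in ("r1", "r2"):
            ess = effective_sample_size(ss.inclusion_series(rid))
            tol = 3 * math.sqrt(expected[rid] * (1 - expected[rid]) / ess)
            assert abs(prof[rid] - expected[rid]) < tol

    def test_hastings_mode_converges_to_parsimony_law(self, t1):
        cfg = toy_config(seed=13, proposal_mode=HASTINGS_CORRECTED)
        prof = estimate_marginals(run_chain(t1, cfg))
        assert prof["r1"] == pytest.approx(T1_P, abs=0.02)

    def test_random_valid_init_reaches_same_law(self, shared_chain):
        exact = exact_marginals(shared_chain, lam=1.0)
        cfg = toy_config(
            seed=4, proposal_mode=HASTINGS_CORRECTED, init_mode="random_valid"
        )
        prof = estimate_marginals(run_chain(shared_chain, cfg))
        for rid, p in exact.items():
            assert prof[rid] == pytest.approx(p, abs=0.03)

    def test_different_seeds_agree_within_mc_tolerance(self, shared_chain):
        cfgs = [toy_config(seed=s, n_samples=10_000) for s in (21, 22)]
        profs = [estimate_marginals(run_chain(shared_chain, c)) for c in cfgs]
        for rid in shared_chain.reaction_ids:
            assert profs[0][rid] == pytest.approx(profs[1][rid], abs=0.03)

    def test_invalid_redraws_not_counted_as_steps(self, t1):
        ss = run_chain(t1, toy_config(seed=1, n_samples=1_000))
        assert ss.n_valid_proposals == 2_000 + 1_000 * 50  # burn-in + S*B
        assert ss.n_invalid_draws > 0


class TestEstimates:
    def test_counting_definition(self, t1):
        samples = np.array([[1, 0], [1, 1]], dtype=np.uint8)
        ss = SampleSet(
            samples=samples,
            reaction_ids=("r1", "r2"),
            network=t1,
            config=ChainConfig(n_samples=2, batch_size=1, burn_in_steps=0),
            acceptance_rate=1.0,
            n_valid_proposals=2,
            n_invalid_draws=0,
            min_subnetwork=t1.subnetwork({"r1"}),
            min_metabolite_count=2,
        )
        prof = estimate_marginals(ss)
        assert prof["r1"] == 1.0
        assert prof["r2"] == 0.5

    def test_t1_symmetry_of_marginals(self, t1):
        prof = estimate_marginals(run_chain(t1, toy_config(seed=17)))
        assert prof["r1"] == pytest.approx(prof["r2"], abs=0.02)

    def test_profile_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            MarginalProfile(probabilities={"r1": 1.2})


class TestDiagnostics:
    def test_ergodic_trace_is_running_mean(self, t1):
        ss = run_chain(t1, toy_config(seed=1, n_samples=1_000))
        trace = ergodic_average_trace(ss, "r1")
        series = ss.inclusion_series("r1").astype(float)
        assert len(trace) == 1_000
        assert trace[0] == series[0]
        assert trace[3] == pytest.approx(series[:4].mean())
        assert trace[-1] == pytest.approx(estimate_marginals(ss)["r1"])

    def test_trace_of_forced_reaction_is_constant_one(self, forced_net):
        ss = run_chain(forced_net, toy_config(seed=1, n_samples=500))
        assert np.all(ergodic_average_trace(ss, "r2") == 1.0)

    def test_unknown_reaction_raises(self, t1):
        ss = run_chain(t1, toy_config(seed=1, n_samples=100))
        with pytest.raises(KeyError):
            ergodic_average_trace(ss, "nope")

    def test_autocorrelation_decreases_with_thinning(self):
        net = generate_network(small_generated_params(3))
        cfg = ChainConfig(lam=1.0, seed=8, burn_in_steps=2_000, n_samples=1)
        # pick a promiscuous, non-forced reaction so inclusion fluctuates
        free = sorted(set(net.reactions) - forced_reactions(net))
        corr = batch_autocorrelation(net, cfg, free[0], [1, 8, 64], n_points=1_500)
        finite = {b: c for b, c in corr.items() if not math.isnan(c)}
        assert finite[1] > finite[64]

    def test_constant_series_flagged_degenerate(self, forced_net):
        cfg = ChainConfig(lam=1.0, seed=8, burn_in_steps=500, n_samples=1)
        corr = batch_autocorrelation(forced_net, cfg, "r2", [1, 4], n_points=500)
        assert all(math.isnan(c) for c in corr.values())

    def test_iid_series_has_negligible_effective_correlation(self):
        rng = np.random.default_rng(0)
        series = (rng.random(5_000) < 0.4).astype(float)
        rho = np.corrcoef(series[:-1], series[1:])[0, 1]
        assert abs(rho) < 3 / math.sqrt(len(series))
        assert effective_sample_size(series) > 0.8 * len(series)


class TestMaxLikelihoodSubnetwork:
    def test_t1_minimum_is_a_singleton(self, t1):
        ss = run_chain(t1, toy_config(seed=3, n_samples=2_000))
        sub, count = max_likelihood_subnetwork(ss)
        assert count == 2
        assert sub.included_reactions in ({"r1"}, {"r2"})

    def test_matches_exact_minimum_on_generated_networks(self):
        from parsnet import exact_min_metabolite_subnetwork

        for seed in (0, 2):
            net = generate_network(small_generated_params(seed))
            _, exact_count, _ = exact_min_metabolite_subnetwork(net)
            ss = run_chain(
                net,
                ChainConfig(
                    lam=1.0, batch_size=20, burn_in_steps=5_000, n_samples=5_000, seed=seed
                ),
            )
            sub, count = max_likelihood_subnetwork(ss)
            assert count == exact_count
            assert sub.is_valid()
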