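"""Mutation-selection dynamics: covariance fixed point, fitness, mutation
proposals, run determinism and leader/follower classification."""

import math

import numpy as np
import pytest

from collnav import (
    AgentGenome,
    DegenerateEquilibriumError,
    EvolutionConfig,
    HomogeneousParams,
    bifurcation_scan,
    classify_outcome,
    equilibrium_covariance,
    equilibrium_sigma,
    evolve,
    fitness,
    propose_mutation,
    simulate_heterogeneous,
)

from conftest import derived_seed


class TestEquilibriumCovariance:
    def test_no_social_coupling(self):
        gen = [AgentGenome(1.0, 1.5, 2.0), AgentGenome(1.0, 0.7, 1.0)]
        cov, sigma = equilibrium_covariance(gen)
        assert cov[0, 1] == 0.0
        assert sigma[0] == pytest.approx(1.5)
        assert sigma[1] == pytest.approx(0.7)

    @pytest.mark.parametrize("w,gamma,n", [(0.5, 1.0, 2), (0.2, 0.5, 5), (0.9, 3.0, 10)])
    def test_homogeneous_genomes_match_closed_form(self, w, gamma, n):
        gen = [AgentGenome(w, 1.0, gamma)] * n
        cov, sigma = equilibrium_covariance(gen)
        st = equilibrium_sigma(HomogeneousParams(n=n, gamma=gamma, w=w))
        assert sigma[0] == pytest.approx(st.sigma, abs=1e-10)
        assert cov[0, 1] / cov[0, 0] == pytest.approx(st.rho, abs=1e-10)

    def test_covariance_is_symmetric_psd(self, rng):
        gen = [AgentGenome(rng.uniform(0.05, 1), rng.exponential() + 0.1,
                           rng.exponential() + 0.1) for _ in range(6)]
        cov, _ = equilibrium_covariance(gen)
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_matches_monte_carlo(self):
        gen = [AgentGenome(0.9, 0.5, 2.0), AgentGenome(0.1, 3.0, 0.3),
               AgentGenome(0.5, 1.0, 1.0), AgentGenome(0.3, 2.0, 0.5)]
        cov, _ = equilibrium_covariance(gen)
        sim = simulate_heterogeneous(gen, T=200, R=2000, seed=11)
        assert np.all(np.abs(sim.cov_hat - cov) <= 3 * sim.cov_se)

    def test_all_zero_weightings_degenerate(self):
        gen = [AgentGenome(0.0, 1.0, 1.0)] * 3
        with pytest.raises(DegenerateEquilibriumError):
            equilibrium_covariance(gen)


class TestFitness:
    def test_direct_substitution(self):
        gen = [AgentGenome(1.0, 1.0, 1.0)] * 2
        assert fitness(0, gen, k=1.0) == pytest.approx(-3.0)

    def test_cost_grows_as_gamma_precision_rises(self):
        base = [AgentGenome(1.0, 1.0, 1.0), AgentGenome(1.0, 1.0, 1.0)]
        finer = [AgentGenome(1.0, 1.0, 0.5), AgentGenome(1.0, 1.0, 1.0)]
        # w=1 everywhere: sigma unaffected by gamma, only the cost term moves
        assert fitness(0, finer, k=1.0) < fitness(0, base, k=1.0)


class TestProposeMutation:
    def test_zero_sd_identity(self, rng):
        g = AgentGenome(0.5, 1.0, 1.0)
        g2 = propose_mutation(g, rng, mutation_sd=1e-300)
        assert g2.w == pytest.approx(g.w, abs=1e-12)
        assert g2.epsilon == pytest.approx(g.epsilon, rel=1e-12)

    def test_proposal_scale(self, rng):
        g = AgentGenome(0.5, 1.0, 1.0)
        props = [propose_mutation(g, rng) for _ in range(10_000)]
        assert np.std([p.w for p in props]) == pytest.approx(0.01, rel=0.05)
        assert np.std([math.log(p.epsilon) for p in props]) == pytest.approx(0.01, rel=0.05)
        assert np.std([math.log(p.gamma) for p in props]) == pytest.approx(0.01, rel=0.05)

    def test_w_clipped_to_unit_interval(self, rng):
        g = AgentGenome(1.0, 1.0, 1.0)
        assert all(propose_mutation(g, rng).w <= 1.0 for _ in range(1000))
        g = AgentGenome(0.0, 1.0, 1.0)
        assert all(propose_mutation(g, rng).w >= 0.0 for _ in range(1000))


class TestClassifyOutcome:
    @pytest.mark.parametrize("ws,label", [
        ((0.95, 0.03), "leader_follower"),
        ((0.9, 0.88), "common_strategy"),
        ((0.5, 0.5), "common_strategy"),
    ])
    def test_threshold_rule(self, ws, label):
        gen = [AgentGenome(w, 1.0, 1.0) for w in ws]
        assert classify_outcome(gen) == label


class TestEvolve:
    def test_deterministic_given_seed(self):
        cfg = EvolutionConfig(n=2, k=1.0, steps=3000, seed=77)
        t1, t2 = evolve(cfg), evolve(cfg)
        assert np.array_equal(t1.snapshots, t2.snapshots)
        assert np.array_equal(t1.accepted, t2.accepted)
        assert [g.w for g in t1.final_genomes] == [g.w for g in t2.final_genomes]

    def test_trace_shape_contract(self):
        cfg = EvolutionConfig(n=3, k=1.0, steps=1000, thin=100, seed=5)
        tr = evolve(cfg)
        assert len(tr.snapshot_steps) == 1000 // 100 + 1
        assert tr.snapshots.shape == (11, 3, 3)
        assert tr.accepted.shape == (1000,)
        assert tr.outcome in ("leader_follower", "common_strategy")

    def test_accepted_mutations_increase_actor_fitness(self):
        cfg = EvolutionConfig(n=2, k=1.0, steps=2000, seed=9, record_fitness=True)
        tr = evolve(cfg)
        acc = tr.accepted
        assert np.all(tr.fitness_after[acc] > tr.fitness_before[acc])
        rej = ~acc & np.isfinite(tr.fitness_after)
        assert np.all(tr.fitness_after[rej] <= tr.fitness_before[rej])

    def test_leader_profile_in_divergent_runs(self):
        # the max-w agent should also be the one with the best private signal
        # and the least attention to others (highest observation noise)
        found = 0
        for s in range(25):
            tr = evolve(EvolutionConfig(n=2, k=1.0, steps=20_000,
                                        seed=derived_seed(31, s)))
            if tr.outcome != "leader_follower":
                continue
            found += 1
            lead = int(np.argmax([g.w for g in tr.final_genomes]))
            foll = 1 - lead
            assert tr.final_genomes[lead].epsilon < tr.final_genomes[foll].epsilon
            assert tr.final_genomes[lead].gamma > tr.final_genomes[foll].gamma
        assert found >= 10  # divergence is the typical outcome at k=1

    def test_sigma_only_acceptance_drives_used_noise_to_zero(self):
        # with costs ignored, precision is free: each agent sharpens whichever
        # channel it relies on (a channel it ignores feels no selection), and
        # every agent's navigation error collapses
        cfg = EvolutionConfig(n=2, k=1.0, steps=20_000, seed=3, accept_on="sigma")
        tr = evolve(cfg)
        assert all(min(g.epsilon, g.gamma) < 1e-3 for g in tr.final_genomes)
        _, sigma = equilibrium_covariance(tr.final_genomes)
        assert np.all(sigma < 0.01)


class TestBifurcationScan:
    def test_scan_and_critical_k(self):
        template = EvolutionConfig(n=2, k=1.0, steps=20_000, seed=3)
        res = bifurcation_scan([0.5, 1.0, 2.5, 3.0], template, replicates=5)
        low = res.outcomes[0.5] + res.outcomes[1.0]
        high = res.outcomes[2.5] + res.outcomes[3.0]
        assert sum(o == "leader_follower" for o in low) > len(low) / 2
        assert sum(o == "common_strategy" for o in high) > len(high) / 2
        assert res.critical_k is not None and 1.0 <= res.critical_k <= 2.5
        # table contract: one row per (k, replicate, agent)
        assert len(res.rows) == 4 * 5 * 2
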