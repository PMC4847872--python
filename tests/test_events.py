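"""Single-event semantics and rate calibration against analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repliwave.core import (PARASITE, REPLICATOR, SimulationParams, bind,
                            place)
from repliwave.dynamics import (ContractError, attempt_association,
                                attempt_decay, attempt_diffusion,
                                attempt_dissociation, attempt_replication,
                                mutate_trait, run_sweeps, sweep)

from tests.conftest import make_empty


def quiet_params(L=9, **overrides):
    """Params with every rate zero unless overridden (dt stays 0.1)."""
    base = dict(k_diss=0.0, rho=0.0, d=0.0, D=0.0, mu=0.0)
    base.update(overrides)
    return SimulationParams(L=L, **base)


class TestAssociation:
    def test_no_free_neighbours_is_noop(self):
        p, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 2.0)
        before = s.kind.copy()
        assert attempt_association(s, (4, 4), p) is False
        assert np.array_equal(s.kind, before)
        assert s.bond[4, 4] == -1

    def test_contract_errors(self):
        p, s = make_empty(L=9)
        place(s, (1, 1), PARASITE, 1.5)
        with pytest.raises(ContractError):
            attempt_association(s, (0, 0), p)  # empty
        with pytest.raises(ContractError):
            attempt_association(s, (1, 1), p)  # parasite never initiates
        place(s, (4, 4), REPLICATOR, 1.0)
        place(s, (4, 5), REPLICATOR, 1.0)
        bind(s, (4, 4), (4, 5))
        with pytest.raises(ContractError):
            attempt_association(s, (4, 4), p)  # already bound

    def test_partner_choice_weighted_by_beta(self):
        # one free replicator neighbour (weight 1) vs one free parasite with
        # beta=1.7: conditional on firing, the parasite is chosen with
        # probability 1.7/2.7.
        p = quiet_params(L=9)
        fired = 0
        parasite_chosen = 0
        trials = 20000
        for trial in range(trials):
            _, s = make_empty(L=9, seed=trial)
            place(s, (4, 4), REPLICATOR, 1.0)
            place(s, (4, 3), REPLICATOR, 1.0)
            place(s, (4, 5), PARASITE, 1.7)
            if attempt_association(s, (4, 4), p):
                fired += 1
                if s.bond[4, 4] == s.site_index((4, 5)):
                    parasite_chosen += 1
                    assert s.role[4, 5] == 2  # parasite is the template
        # firing probability: 1 - exp(-k_a * mean(1, 1.7) * dt)
        p_fire = -math.expm1(-1.0 * (2.7 / 2) * 0.1)
        assert abs(fired / trials - p_fire) < 4 * math.sqrt(p_fire * (1 - p_fire) / trials)
        frac = parasite_chosen / fired
        expected = 1.7 / 2.7
        assert abs(frac - expected) < 4 * math.sqrt(expected * (1 - expected) / fired)

    @pytest.mark.parametrize("neighbours,rate", [
        # a lone replicator template is bound at rate k_a
        ([((4, 5), REPLICATOR, 1.0)], 1.0),
        # a lone parasite template at rate k_a * beta
        ([((4, 5), PARASITE, 1.7)], 1.7),
        # the total rate follows the mean template weight, so three
        # replicator templates still bind at rate k_a
        ([((4, 5), REPLICATOR, 1.0), ((4, 3), REPLICATOR, 1.0),
          ((3, 4), REPLICATOR, 1.0)], 1.0),
    ])
    def test_association_rate_follows_mean_template_weight(self, neighbours, rate):
        p = quiet_params(L=9)
        fired = 0
        trials = 20000
        for trial in range(trials):
            _, s = make_empty(L=9, seed=trial)
            place(s, (4, 4), REPLICATOR, 1.0)
            for site, kind, trait in neighbours:
                place(s, site, kind, trait)
            fired += attempt_association(s, (4, 4), p)
        expected = -math.expm1(-rate * 0.1)
        assert abs(fired / trials - expected) < 4 * math.sqrt(
            expected * (1 - expected) / trials)

    def test_bound_neighbours_excluded(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 2.0)
        place(s, (4, 5), REPLICATOR, 1.0)
        place(s, (4, 6), REPLICATOR, 1.0)
        bind(s, (4, 5), (4, 6))
        for _ in range(300):
            assert attempt_association(s, (4, 4), p) is False

    def test_pair_equilibrium_matches_two_state_balance(self):
        # two adjacent replicators with only association/dissociation
        # enabled: fraction of time bound ~ (ka_i + ka_j) / (ka_i + ka_j + k_diss)
        p = quiet_params(L=8, k_diss=0.25)
        _, s = make_empty(L=8, seed=42, k_diss=0.25)
        place(s, (3, 3), REPLICATOR, 0.8)
        place(s, (3, 4), REPLICATOR, 0.4)
        bound = 0
        n_sweeps = 40000
        done, _, _ = run_sweeps(s, p, 0)  # warm the kernel path
        for _ in range(n_sweeps):
            run_sweeps(s, p, 1)
            bound += s.bond[3, 3] >= 0
        f = bound / n_sweeps
        expected = 1.2 / (1.2 + 0.25)
        assert abs(f - expected) < 0.03

    def test_zero_ka_never_binds(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 0.0)
        place(s, (4, 5), REPLICATOR, 1.0)
        for _ in range(500):
            assert attempt_association(s, (4, 4), p) is False


class TestDissociation:
    def test_kdiss_zero_complex_is_stable(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 1.0)
        place(s, (4, 5), REPLICATOR, 1.0)
        bind(s, (4, 4), (4, 5))
        for _ in range(300):
            assert attempt_dissociation(s, (4, 4), p) is False
        assert s.bond[4, 4] >= 0

    def test_no_motion_on_dissociation(self):
        p = quiet_params(L=9, k_diss=5.0)
        _, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 1.0)
        place(s, (4, 5), PARASITE, 1.5)
        bind(s, (4, 4), (4, 5))
        while not attempt_dissociation(s, (4, 4), p):
            pass
        assert s.kind[4, 4] == REPLICATOR and s.kind[4, 5] == PARASITE
        assert s.bond[4, 4] == -1 and s.bond[4, 5] == -1
        assert s.role[4, 4] == 0 and s.role[4, 5] == 0

    def test_contract_error_on_unbound(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 1.0)
        with pytest.raises(ContractError):
            attempt_dissociation(s, (4, 4), p)

    def test_lifetime_mean_matches_inverse_kdiss(self):
        # isolated complexes, only dissociation enabled: exponential lifetime
        # with mean 1/k_diss = 4 AUT at k_diss = 0.25
        p = quiet_params(L=64, k_diss=0.25)
        lifetimes = []
        for batch in range(4):
            _, s = make_empty(L=64, seed=100 + batch, k_diss=0.25)
            sites = []
            for bx in range(0, 64, 4):
                for by in range(0, 64, 4):
                    place(s, (bx, by), REPLICATOR, 0.0)
                    place(s, (bx, by + 1), REPLICATOR, 0.0)
                    bind(s, (bx, by), (bx, by + 1))
                    sites.append((bx, by))
            alive = {site: True for site in sites}
            t_formed = {site: 0 for site in sites}
            sweeps = 0
            while any(alive.values()) and sweeps < 4000:
                run_sweeps(s, p, 1)
                sweeps += 1
                for site in sites:
                    if alive[site] and s.bond[site] < 0:
                        alive[site] = False
                        lifetimes.append(sweeps * p.dt)
        lifetimes = np.array(lifetimes)
        mean = lifetimes.mean()
        sigma = 4.0 / math.sqrt(lifetimes.size)
        # discrete-time mean is dt / (1 - exp(-k_diss*dt)) = 4.05 AUT
        assert abs(mean - 4.05) < 3 * sigma
        # exponential shape: sd close to the mean
        assert abs(lifetimes.std() / mean - 1.0) < 0.1


class TestReplication:
    def _complex(self, L=9, seed=0, replicase_ka=1.2, template_kind=REPLICATOR,
                 template_trait=0.6, **overrides):
        p = quiet_params(L=L, rho=1.0, **overrides)
        _, s = make_empty(L=L, seed=seed, rho=1.0, **overrides)
        place(s, (4, 4), REPLICATOR, replicase_ka)
        place(s, (4, 5), template_kind, template_trait)
        bind(s, (4, 4), (4, 5))
        return p, s

    def test_template_is_copied_not_replicase(self):
        for seed in range(200):
            p, s = self._complex(seed=seed)
            if attempt_replication(s, (4, 4), p):
                offspring = np.argwhere((s.kind != 0))
                assert len(offspring) == 3
                new = [tuple(x) for x in offspring if tuple(x) not in ((4, 4), (4, 5))]
                ox, oy = new[0]
                assert s.kind[ox, oy] == REPLICATOR
                assert s.trait[ox, oy] == 0.6  # the template's k_a, pre-mutation
                # complex broke, both parents unbound in place
                assert s.bond[4, 4] == -1 and s.bond[4, 5] == -1
                return
        pytest.fail("replication never fired in 200 attempts at p~0.095")

    def test_parasite_template_yields_parasite(self):
        for seed in range(200):
            p, s = self._complex(seed=seed, template_kind=PARASITE,
                                 template_trait=1.7)
            if attempt_replication(s, (4, 4), p):
                new = np.argwhere(s.kind == PARASITE)
                assert len(new) == 2
                return
        pytest.fail("replication never fired")

    def test_age_gate_blocks_young_complex(self):
        p, s = self._complex(dt_repl=4.0)
        s.age[4, 4] = 20  # 2 AUT < 4 AUT
        for _ in range(300):
            assert attempt_replication(s, (4, 4), p) == 0

    def test_age_gate_opens_at_dt_repl(self):
        p, s = self._complex(dt_repl=4.0)
        s.age[4, 4] = 40  # exactly 4 AUT: >= comparison
        fired = any(attempt_replication(s, (4, 4), p) for _ in range(300))
        assert fired

    def test_no_empty_space_blocks_replication(self):
        p, s = self._complex()
        for x in range(3, 6):
            for y in range(3, 7):
                if (x, y) not in ((4, 4), (4, 5)) and s.kind[x, y] == 0:
                    place(s, (x, y), REPLICATOR, 0.0)
        for _ in range(300):
            assert attempt_replication(s, (4, 4), p) == 0

    def test_contract_error_on_template_or_unbound(self):
        p, s = self._complex()
        with pytest.raises(ContractError):
            attempt_replication(s, (4, 5), p)  # template, not replicase
        with pytest.raises(ContractError):
            attempt_replication(s, (2, 2), p)  # empty

    def test_offspring_per_association_decreases_with_dt_repl(self):
        # renewal oracle for an isolated pair with dissociation checked before
        # replication each sweep:
        #   P(replicate | complex formed) =
        #     (1-p_diss)^(min_age-1) * (1-p_diss) * p_rho / (1 - (1-p_diss)(1-p_rho))
        p_diss = -math.expm1(-0.25 * 0.1)
        p_rho = -math.expm1(-1.0 * 0.1)
        geo = (1 - p_diss) * p_rho / (1 - (1 - p_diss) * (1 - p_rho))

        results = {}
        for dt_repl in (0.0, 2.0, 4.0):
            p = quiet_params(L=9, k_diss=0.25, rho=1.0, dt_repl=dt_repl)
            _, s = make_empty(L=9, seed=17, k_diss=0.25, rho=1.0, dt_repl=dt_repl)
            place(s, (4, 4), REPLICATOR, 1.0)
            place(s, (4, 5), REPLICATOR, 1.0)
            n_assoc = n_repl = 0
            from repliwave import _kernel as K
            counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
            for _ in range(30000):
                run_sweeps(s, p, 1, counters=counters)
                # keep the scenario fixed: remove offspring, keep the pair
                for (x, y) in np.argwhere(s.kind != 0):
                    if (x, y) not in ((4, 4), (4, 5)):
                        partner = s.bond[x, y]
                        if partner >= 0:
                            s.bond.reshape(-1)[partner] = -1
                            s.role.reshape(-1)[partner] = 0
                            s.age.reshape(-1)[partner] = 0
                        s.kind[x, y] = 0
                        s.trait[x, y] = 0.0
                        s.bond[x, y] = -1
                        s.role[x, y] = 0
                        s.age[x, y] = 0
            n_assoc = counters[K.C_ASSOC]
            n_repl = counters[K.C_REPL_R]
            results[dt_repl] = (n_repl / n_assoc, n_assoc)
        # monotone non-increasing in dt_repl
        assert results[0.0][0] >= results[2.0][0] >= results[4.0][0]
        # dt_repl = 0 matches the baseline renewal oracle
        ratio0, n0 = results[0.0]
        assert abs(ratio0 - geo) < 4 * math.sqrt(geo * (1 - geo) / n0)
        # dt_repl = 4 matches the age-gated oracle
        min_age = 40
        gated = (1 - p_diss) ** (min_age - 1) * geo
        ratio4, n4 = results[4.0]
        assert abs(ratio4 - gated) < 4 * math.sqrt(gated * (1 - gated) / n4) + 0.01


class TestMutation:
    def test_mu_zero_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_trait(1.3, 0.0, 0.05, (0, 2), rng) == 1.3

    def test_support_is_half_delta(self):
        rng = np.random.default_rng(1)
        vals = [mutate_trait(1.0, 1.0, 0.05, (0, 2), rng) for _ in range(2000)]
        assert min(vals) >= 0.975 and max(vals) <= 1.025
        assert min(vals) < 0.99 and max(vals) > 1.01  # actually spreads

    def test_clipping_at_bounds(self):
        rng = np.random.default_rng(2)
        vals = [mutate_trait(1.999, 1.0, 0.05, (0, 2), rng) for _ in range(500)]
        assert max(vals) <= 2.0

    @given(st.floats(0, 2), st.floats(0, 1), st.floats(0, 0.5),
           st.integers(0, 10000))
    def test_stays_within_bounds(self, value, mu, delta, seed):
        rng = np.random.default_rng(seed)
        out = mutate_trait(value, mu, delta, (0.0, 2.0), rng)
        assert 0.0 <= out <= 2.0


class TestDecay:
    def test_template_decay_frees_replicase(self):
        p = quiet_params(L=9, d=5.0)
        _, s = make_empty(L=9, d=5.0)
        place(s, (4, 4), REPLICATOR, 1.0)
        place(s, (4, 5), PARASITE, 1.5)
        bind(s, (4, 4), (4, 5))
        while not attempt_decay(s, (4, 5), p):
            pass
        assert s.kind[4, 5] == 0
        assert s.kind[4, 4] == REPLICATOR
        assert s.bond[4, 4] == -1 and s.role[4, 4] == 0

    def test_d_zero_never_decays(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        place(s, (4, 4), REPLICATOR, 1.0)
        for _ in range(500):
            assert attempt_decay(s, (4, 4), p) is False

    def test_contract_error_on_empty(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        with pytest.raises(ContractError):
            attempt_decay(s, (0, 0), p)

    def test_population_decays_exponentially(self):
        # non-replicating molecules with d = 0.03: per-sweep survival is
        # exactly exp(-d*dt), so N(t) tracks N0*exp(-d*t)
        d = 0.03
        p = quiet_params(L=64, d=d)
        from repliwave.core import InitSpec, init_lattice
        s = init_lattice(SimulationParams(L=64, d=d, seed=3), InitSpec(
            density_replicators=0.3, ka_init=0.0), seed=3)
        n0 = int((s.kind != 0).sum())
        for t in (100.0, 200.0, 300.0):
            run_sweeps(s, p, 1000)
            n = int((s.kind != 0).sum())
            surv = math.exp(-d * t)
            sigma = math.sqrt(n0 * surv * (1 - surv))
            assert abs(n - n0 * surv) < 4 * sigma


class TestDiffusion:
    def test_D_zero_never_moves(self):
        p = quiet_params(L=16)
        _, s = make_empty(L=16)
        place(s, (8, 8), REPLICATOR, 0.0)
        run_sweeps(s, p, 500)
        assert s.kind[8, 8] == REPLICATOR

    def test_msd_matches_step_kernel(self):
        # single molecule random walk: every sweep it hops to a uniform Moore
        # neighbour with probability p = 1-exp(-D*dt).  Independent oracle by
        # direct simulation of that step kernel with numpy.
        D, dt, n_sweeps, trials = 0.1, 0.1, 500, 400
        p_move = -math.expm1(-D * dt)
        rng = np.random.default_rng(99)
        offsets = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                            (1, -1), (1, 0), (1, 1)])
        oracle_sq = []
        for _ in range(trials):
            moves = rng.random(n_sweeps) < p_move
            steps = offsets[rng.integers(0, 8, size=n_sweeps)]
            disp = (steps * moves[:, None]).sum(axis=0)
            oracle_sq.append(disp @ disp)
        oracle_msd = float(np.mean(oracle_sq))

        p = quiet_params(L=32, D=D)
        sim_sq = []
        for trial in range(trials):
            _, s = make_empty(L=32, seed=trial, D=D)
            place(s, (16, 16), REPLICATOR, 0.0)
            run_sweeps(s, p, n_sweeps)
            pos = np.argwhere(s.kind != 0)[0]
            dxy = pos - np.array([16, 16])
            dxy = (dxy + 16) % 32 - 16  # minimum image
            sim_sq.append(dxy @ dxy)
        sim_msd = float(np.mean(sim_sq))
        se = np.std(oracle_sq) / math.sqrt(trials) + np.std(sim_sq) / math.sqrt(trials)
        assert abs(sim_msd - oracle_msd) < 4 * se
        # and both agree with the closed form 1.5 * p * n
        assert abs(oracle_msd - 1.5 * p_move * n_sweeps) < 4 * se

    def test_complex_moves_rigidly(self):
        p = quiet_params(L=16, D=5.0)
        _, s = make_empty(L=16, D=5.0)
        place(s, (8, 8), REPLICATOR, 1.0)
        place(s, (8, 9), PARASITE, 1.5)
        bind(s, (8, 8), (8, 9))
        for _ in range(300):
            occ = np.argwhere(s.kind != 0)
            site = tuple(occ[0])
            if s.role[site] != 1:
                site = tuple(occ[1])
            attempt_diffusion(s, site, p)
            # bond symmetry and adjacency preserved
            occ = np.argwhere(s.kind != 0)
            assert len(occ) == 2
            a, b = (tuple(x) for x in occ)
            ia, ib = s.site_index(a), s.site_index(b)
            assert s.bond[a] == ib and s.bond[b] == ia
            dx = min(abs(a[0] - b[0]), 16 - abs(a[0] - b[0]))
            dy = min(abs(a[1] - b[1]), 16 - abs(a[1] - b[1]))
            assert max(dx, dy) == 1

    def test_contract_error_on_empty(self):
        p = quiet_params(L=9)
        _, s = make_empty(L=9)
        with pytest.raises(ContractError):
            attempt_diffusion(s, (0, 0), p)
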