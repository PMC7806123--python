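"""Monte Carlo engine: Glauber rule, heat bath, schedules, reproducibility,
hard-core enforcement, and equilibrium sampling."""

import numpy as np
import pytest

from conftest import chi2_pvalue
from knotfold.energy import EnergyModel, SolitonSegment, angular_free_energy, has_hard_core_violation
from knotfold.frenet import AngularConformation, CAlphaChain
from knotfold.mc import (
    MCState,
    Schedule,
    glauber_acceptance_probability,
    glauber_torsion_step,
    heatbath_theta_step,
    run_cycle,
    run_ensemble,
    run_stage,
    _theta_energy_profile,
)


def open_system(n=10, c=1.0, a=0.0, b=0.0, d=0.0, lam=1.0, m=0.3, beta=1.0,
                hb_ratio=1.0, seed=0, radius=3.8):
    """Near-straight chain whose hard core can never trigger: the torsion
    and bond-angle moves sample their ideal conditional distributions."""
    model = EnergyModel([SolitonSegment(1, n, lam, m, a, b, c, d)],
                        hard_core_radius=radius)
    angles = AngularConformation(np.full(n - 2, 0.3), np.zeros(n - 3))
    return MCState(angles, model, beta=beta, rng=np.random.default_rng(seed),
                   hb_ratio=hb_ratio)


class TestGlauberRule:
    def test_half_at_zero(self):
        assert glauber_acceptance_probability(0.0, beta=3.7) == 0.5

    def test_quarter_at_log_three(self):
        assert glauber_acceptance_probability(np.log(3.0), 1.0) == pytest.approx(0.25)

    def test_detailed_balance_identity(self):
        for x in np.linspace(-20, 20, 41):
            p, q = glauber_acceptance_probability(x, 1.0), glauber_acceptance_probability(-x, 1.0)
            assert p / q == pytest.approx(np.exp(-x), rel=1e-12)

    def test_empirical_acceptance_matches_rule(self):
        # end-to-end: run 1e5 torsion steps and compare the realized number
        # of acceptances with the sum of per-proposal Glauber probabilities
        state = open_system(n=12, c=1.0, beta=1.5, seed=42)
        from knotfold.energy import delta_free_energy
        from knotfold.frenet import wrap_angle

        n_trials = 100_000
        rng_shadow = np.random.default_rng(42)
        expected_p = np.empty(n_trials)
        accepted = np.empty(n_trials, dtype=bool)
        site = 5
        for k in range(n_trials):
            old = state.angles.phi[site - 2]
            new = float(wrap_angle(old + 0.5 * np.pi * rng_shadow.standard_normal()))
            expected_p[k] = glauber_acceptance_probability(
                delta_free_energy(state.angles, state.model, site, "phi", new),
                state.beta)
            u = rng_shadow.random()
            accepted[k] = u < expected_p[k]
            if accepted[k]:
                state.angles.phi[site - 2] = new
        n_acc = accepted.sum()
        mu = expected_p.sum()
        sigma = np.sqrt(np.sum(expected_p * (1 - expected_p)))
        assert abs(n_acc - mu) < 3 * sigma

    def test_step_function_matches_shadowed_rng(self):
        # the public step consumes (normal, uniform) per proposal: replaying
        # the same stream reproduces its decisions exactly
        state = open_system(n=12, c=1.0, beta=1.5, seed=7)
        shadow = open_system(n=12, c=1.0, beta=1.5, seed=7)
        rng = np.random.default_rng(7)
        from knotfold.energy import delta_free_energy
        from knotfold.frenet import wrap_angle

        for _ in range(500):
            old = shadow.angles.phi[3]
            new = float(wrap_angle(old + 0.5 * np.pi * rng.standard_normal()))
            dF = delta_free_energy(shadow.angles, shadow.model, 5, "phi", new)
            expect = rng.random() < glauber_acceptance_probability(dF, shadow.beta)
            got = glauber_torsion_step(state, 5)
            assert got == expect
            if expect:
                shadow.angles.phi[3] = new
        np.testing.assert_array_equal(state.angles.phi, shadow.angles.phi)


class TestHeatBath:
    def test_zero_temperature_limit_recovers_mode(self):
        state = open_system(n=10, lam=2.0, m=1.1, beta=1.0, hb_ratio=1e12, seed=1)
        site = 4
        xs = np.linspace(0, np.pi, 4097)[:-1]
        F = _theta_energy_profile(state.angles, state.model, site, xs)
        mode = xs[np.argmin(F)]
        for _ in range(20):
            heatbath_theta_step(state, site)
            assert abs(state.angles.theta[site - 1] - mode) < np.pi / 1024 * 2
            state.angles.theta[site - 1] = 0.3  # reset

    def test_infinite_temperature_is_uniform(self):
        from scipy.stats import kstest

        # the hard core is disabled: at infinite temperature, draws near
        # theta = pi fold the chain onto itself and would be vetoed
        # sterically, distorting uniformity
        state = open_system(n=10, beta=1e-300, hb_ratio=0.0, seed=2, radius=0.0)
        draws = np.empty(10_000)
        for k in range(draws.size):
            heatbath_theta_step(state, 5)
            draws[k] = state.angles.theta[4]
            state.angles.theta[4] = 0.3
        assert kstest(draws / np.pi, "uniform").pvalue > 0.01

    def test_samples_match_boltzmann_density(self):
        # chi-square against the numerically normalized conditional density
        state = open_system(n=10, lam=1.0, m=1.0, beta=1.0, hb_ratio=3.0, seed=3)
        site = 5
        n_draws = 100_000
        draws = np.empty(n_draws)
        for k in range(n_draws):
            heatbath_theta_step(state, site)
            draws[k] = state.angles.theta[site - 1]
            state.angles.theta[site - 1] = 0.3
        edges = np.linspace(0, np.pi, 257)
        counts, _ = np.histogram(draws, bins=edges)
        fine = np.linspace(0, np.pi, 2**15 + 1)
        dens = np.exp(-state.beta_hb * (
            _theta_energy_profile(state.angles, state.model, site, fine)
            - _theta_energy_profile(state.angles, state.model, site, fine).min()))
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
        cdf /= cdf[-1]
        expected = np.diff(np.interp(edges, fine, cdf)) * n_draws
        assert chi2_pvalue(counts, expected) > 0.01


class TestSchedules:
    def test_unit_multiplier_keeps_beta(self):
        state = open_system(seed=4)
        sched = Schedule(1.0, 1, 0, 0, 1.0, 1.0, record_stride=0)
        run_stage(state, 500, 1.0, sched)
        assert state.beta == 1.0

    def test_geometric_beta_evolution(self):
        state = open_system(seed=5)
        sched = Schedule(1.0, 1, 0, 0, 1.0, 1.0, record_stride=0)
        run_stage(state, 300, 1.01, sched)
        assert state.beta == pytest.approx(1.01**300, rel=1e-9)

    def test_from_beta_range_endpoints(self):
        s = Schedule.from_beta_range(1000.0, 0.1, 200, 50, 400)
        assert 1000.0 * s.heating_multiplier**200 == pytest.approx(0.1, rel=1e-9)
        assert 0.1 * s.cooling_multiplier**400 == pytest.approx(1000.0, rel=1e-9)


class TestReproducibility:
    def test_identical_seed_identical_trajectory(self, two_segment_decoy):
        model, native = two_segment_decoy
        sched = Schedule.from_beta_range(50.0, 0.5, 2000, 500, 2000,
                                         record_stride=500, hb_ratio=10.0,
                                         n_theta_bins=128)
        a = run_cycle(model, native, sched, seed=3, classify=False)
        b = run_cycle(model, native, sched, seed=3, classify=False)
        assert a.records.equals(b.records)
        np.testing.assert_array_equal(a.final_chain.positions, b.final_chain.positions)

    def test_kernel_equals_python_reference(self, two_segment_decoy):
        model, native = two_segment_decoy
        sched = Schedule.from_beta_range(50.0, 0.5, 1000, 300, 1000,
                                         record_stride=250, hb_ratio=10.0,
                                         n_theta_bins=128)
        a = run_cycle(model, native, sched, seed=9, classify=False, use_kernel=True)
        b = run_cycle(model, native, sched, seed=9, classify=False, use_kernel=False)
        np.testing.assert_array_equal(a.final_chain.positions, b.final_chain.positions)
        np.testing.assert_array_equal(a.phi_records, b.phi_records)
        # identical trajectories; the cached-energy column may differ in the
        # last ulp (compiled fused-multiply-add accumulation)
        for col in ("step", "stage", "log10_beta", "rmsd"):
            np.testing.assert_array_equal(a.records[col], b.records[col])
        for col in ("energy", "rg"):
            np.testing.assert_allclose(a.records[col], b.records[col],
                                       rtol=1e-12, atol=1e-12)


class TestTrajectoryContracts:
    def test_hard_core_never_violated_along_trajectory(self, two_segment_decoy):
        model, native = two_segment_decoy
        sched = Schedule.from_beta_range(50.0, 0.2, 3000, 1000, 3000,
                                         record_stride=200, hb_ratio=20.0,
                                         n_theta_bins=128)
        for seed in (1, 2):
            cyc = run_cycle(model, native, sched, seed=seed, classify=False)
            assert np.isfinite(cyc.records["rg"]).all()
            for snapshot in cyc.pos_records:
                assert not has_hard_core_violation(
                    CAlphaChain(snapshot), model.hard_core_radius,
                    model.min_sequence_separation_for_core)

    def test_energy_cache_matches_full_recomputation(self, two_segment_decoy):
        model, native = two_segment_decoy
        st = MCState.from_multisoliton(native, 5.0, seed=5, hb_ratio=10.0)
        run_stage(st, 2000, 1.0, Schedule(5.0, 1, 0, 0, 1.0, 1.0,
                                          record_stride=0, hb_ratio=10.0,
                                          n_theta_bins=128))
        assert st.energy == pytest.approx(
            angular_free_energy(st.angles, st.model), abs=1e-9)
        assert not has_hard_core_violation(st.chain)

    def test_zero_length_stages_return_native(self, slipknot_system):
        chain, model, native = slipknot_system
        sched = Schedule(100.0, 0, 0, 0, 1.0, 1.0, record_stride=0)
        cyc = run_cycle(model, native, sched, seed=0, classify=True)
        np.testing.assert_allclose(
            cyc.final_chain.positions, native.chain().positions, atol=1e-12)
        assert cyc.final_class == "native_slipknot"

    def test_heating_expands_the_chain(self, two_segment_decoy):
        model, native = two_segment_decoy
        from knotfold.observables import radius_of_gyration

        sched = Schedule.from_beta_range(50.0, 0.05, 4000, 0, 0,
                                         record_stride=0, hb_ratio=20.0,
                                         n_theta_bins=128)
        rgs = []
        for seed in range(5):
            cyc = run_cycle(model, native, sched, seed=seed, classify=False)
            rgs.append(radius_of_gyration(cyc.final_chain))
        native_rg = radius_of_gyration(native.chain())
        assert np.mean(rgs) > native_rg  # molten ensemble is swollen


class TestEnsemble:
    def test_single_cycle_sd_undefined_and_fractions_sum(self, two_segment_decoy):
        model, native = two_segment_decoy
        sched = Schedule.from_beta_range(50.0, 0.5, 500, 100, 500,
                                         record_stride=200, hb_ratio=10.0,
                                         n_theta_bins=128)
        summary, cycles = run_ensemble(model, native, sched, 1, seed0=0,
                                       classify=False)
        assert np.isnan(summary.rg_sd).all()
        summary3, _ = run_ensemble(model, native, sched, 3, seed0=0,
                                   classify=True)
        assert sum(summary3.class_fractions.values()) == pytest.approx(1.0)
        assert (summary3.rg_sd >= 0).all()

    def test_native_start_has_zero_torsion_fluctuation(self, two_segment_decoy):
        model, native = two_segment_decoy
        sched = Schedule.from_beta_range(50.0, 0.5, 400, 0, 0,
                                         record_stride=100, hb_ratio=10.0,
                                         n_theta_bins=128)
        summary, _ = run_ensemble(model, native, sched, 3, seed0=0, classify=False)
        np.testing.assert_allclose(summary.delta_phi[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(summary.delta_phi_spread[0], 0.0, atol=1e-7)


class TestEquilibrium:
    def test_fixed_beta_torsion_marginals_match_boltzmann(self):
        """Long-run Glauber sampling on a four-torsion-site system against
        dense-quadrature Boltzmann marginals (the conditional torsion terms
        are site-local, so the marginals factorize exactly)."""
        n = 7  # phi sites 2..5
        beta = 1.0
        model = EnergyModel([SolitonSegment(1, n, 1.0, 0.3, a=0.4, b=0.2,
                                            c=1.0, d=0.3)])
        angles = AngularConformation(np.full(n - 2, 0.3), np.zeros(n - 3))
        state = MCState(angles, model, beta=beta,
                        rng=np.random.default_rng(11), hb_ratio=1.0)
        sched = Schedule(beta, 1, 0, 0, 1.0, 1.0, record_stride=25,
                         theta_move_probability=0.0)
        n_steps = 400_000
        n_rec = n_steps // 25 + 1
        import knotfold._mc_kernel as _k

        rec = np.full((n_rec, _k.NREC_FIELDS), np.nan)
        rec_pos = np.zeros((n_rec, n, 3))
        rec_phi = np.zeros((n_rec, n - 3))
        run_stage(state, n_steps, 1.0, sched, 0, rec, rec_pos, rec_phi)
        burn = n_rec // 10
        samples = rec_phi[burn:-1]  # last row is the unwritten final slot
        # quadrature marginal per site
        seg = model.segments[0]
        t2 = 0.3**2
        fine = np.linspace(-np.pi, np.pi, 2**15 + 1)
        local = (0.5 * seg.d * t2 * fine**2 + 0.5 * seg.c * fine**2
                 - seg.b * t2 * fine - seg.a * fine)
        dens = np.exp(-beta * (local - local.min()))
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
        cdf /= cdf[-1]
        edges = np.linspace(-np.pi, np.pi, 33)
        expected_frac = np.diff(np.interp(edges, fine, cdf))
        for site_col in range(samples.shape[1]):
            counts, _ = np.histogram(samples[:, site_col], bins=edges)
            p = chi2_pvalue(counts, expected_frac * counts.sum())
            assert p > 0.01, f"site {site_col + 2}: p = {p:.4f}"
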