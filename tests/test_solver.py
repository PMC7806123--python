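"""Critical points of the free energy: closed-form torsion stationarity,
gradient consistency, relaxation, segmentation, and parameter fitting."""

import numpy as np
import pytest

from knotfold.energy import EnergyModel, SolitonSegment, angular_free_energy
from knotfold.frenet import AngularConformation, angles_to_coords, coords_to_angles
from knotfold.observables import rmsd_superposed
from knotfold.solver import (
    RelaxationError,
    critical_point_residuals,
    fit_model,
    pinned_model,
    relax_to_critical_point,
    segment_decoy,
    solve_phi_given_theta,
)
from test_energy import random_model, random_state, single_segment_model


class TestTorsionStationarity:
    def test_zero_theta(self):
        seg = SolitonSegment(1, 10, 1.0, 1.0, a=0.8, b=0.3, c=2.0, d=0.1)
        assert solve_phi_given_theta(0.0, seg) == pytest.approx(0.4)

    def test_unit_case(self):
        seg = SolitonSegment(1, 10, 1.0, 1.0, a=0.0, b=1.0, c=1.0, d=1.0)
        assert solve_phi_given_theta(1.0, seg) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_partial_derivative_vanishes(self, seed):
        rng = np.random.default_rng(seed)
        ang = random_state(12, seed=seed)
        seg = SolitonSegment(1, 10, 1.0, 1.0, a=rng.normal(), b=rng.normal(),
                             c=rng.uniform(1, 2), d=rng.uniform(0, 0.3))
        model = EnergyModel([seg])
        site = 5
        ang.phi[site - 2] = solve_phi_given_theta(ang.theta[site - 1], seg)
        h = 1e-6
        up, down = ang.copy(), ang.copy()
        up.phi[site - 2] += h
        down.phi[site - 2] -= h
        dF = (angular_free_energy(up, model) - angular_free_energy(down, model)) / (2 * h)
        assert abs(dF) < 1e-8


class TestResiduals:
    def test_uniform_background_is_critical(self):
        # b = d = 0, theta = m, phi = a/c: every residual vanishes,
        # including at the free boundaries
        seg = SolitonSegment(1, 18, 1.4, 1.1, a=0.6, b=0.0, c=1.5, d=0.0)
        model = EnergyModel([seg])
        ang = AngularConformation(np.full(18, 1.1), np.full(17, 0.4))
        r_th, r_ph = critical_point_residuals(ang, model)
        np.testing.assert_allclose(r_th, 0.0, atol=1e-12)
        np.testing.assert_allclose(r_ph, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_residuals_equal_finite_difference_gradient(self, seed):
        ang = random_state(16, seed=seed)
        model = random_model(ang, seed=seed, n_segments=3)
        r_th, r_ph = critical_point_residuals(ang, model)
        h = 1e-6
        for j in range(ang.n_theta):
            up, dn = ang.copy(), ang.copy()
            up.theta[j] += h
            dn.theta[j] -= h
            fd = (angular_free_energy(up, model) - angular_free_energy(dn, model)) / (2 * h)
            assert r_th[j] == pytest.approx(fd, abs=1e-6)
        for j in range(ang.n_phi):
            up, dn = ang.copy(), ang.copy()
            up.phi[j] += h
            dn.phi[j] -= h
            fd = (angular_free_energy(up, model) - angular_free_energy(dn, model)) / (2 * h)
            assert r_ph[j] == pytest.approx(fd, abs=1e-6)


class TestRelaxation:
    def test_known_critical_point_returned_unchanged(self):
        seg = SolitonSegment(1, 14, 1.0, 1.2, a=0.5, b=0.0, c=1.0, d=0.0)
        model = EnergyModel([seg])
        ang = AngularConformation(np.full(14, 1.2), np.full(13, 0.5))
        ms = relax_to_critical_point(ang, model, tol=1e-9)
        np.testing.assert_allclose(ms.angles.theta, ang.theta, atol=1e-12)
        np.testing.assert_allclose(ms.angles.phi, ang.phi, atol=1e-12)

    def test_noisy_init_converges_to_uniform_background(self):
        rng = np.random.default_rng(0)
        seg = SolitonSegment(1, 20, 2.0, 1.2, a=0.3, b=0.0, c=1.0, d=0.0)
        model = EnergyModel([seg])
        ang = AngularConformation(
            np.clip(1.2 + 0.05 * rng.normal(size=20), 0.01, 3.0),
            np.full(19, 0.3))
        ms = relax_to_critical_point(ang, model, tol=1e-9)
        # bulk converges to theta = m (free boundaries make the ends exact too)
        np.testing.assert_allclose(ms.angles.theta[3:-3], 1.2, atol=1e-6)
        np.testing.assert_allclose(ms.angles.phi, 0.3, atol=1e-8)

    @pytest.mark.parametrize("seed", [4, 13, 15])
    def test_energy_not_increased_and_residual_certified(self, seed):
        ang = random_state(18, seed=seed)
        model = random_model(ang, seed=seed)
        F0 = angular_free_energy(ang, model)
        ms = relax_to_critical_point(ang, model, tol=1e-8, max_iter=300)
        assert ms.energy <= F0 + 1e-12
        assert ms.residual_norm < 1e-8
        r_th, r_ph = critical_point_residuals(ms.angles, model)
        assert max(np.abs(r_th).max(), np.abs(r_ph).max()) < 1e-8

    def test_nonconvergence_raises_with_trace(self):
        ang = random_state(18, seed=11)
        model = random_model(ang, seed=11)
        with pytest.raises(RelaxationError) as exc:
            relax_to_critical_point(ang, model, tol=1e-30, max_iter=2)
        assert len(exc.value.trace) >= 2


class TestSegmentation:
    def test_uniform_helix_single_segment(self):
        ang = AngularConformation(np.full(30, np.pi / 2), np.ones(29))
        assert segment_decoy(ang, 1) == [(1, 30)]

    def test_helix_loop_helix_cut_inside_loop(self):
        theta = np.full(40, np.pi / 2)
        theta[18:23] = 0.4  # loop excursion
        ang = AngularConformation(theta, np.ones(39))
        (a0, a1), (b0, b1) = segment_decoy(ang, 2)
        assert 19 <= a1 <= 23  # boundary falls inside the excursion

    @pytest.mark.parametrize("n_segments", [1, 2, 3, 7])
    def test_exact_partition(self, n_segments):
        from knotfold.fixtures import random_chain

        _, ang = random_chain(33, seed=4)
        segm = segment_decoy(ang, n_segments)
        assert segm[0][0] == 1 and segm[-1][1] == ang.n_theta
        for (_, last), (first, _) in zip(segm, segm[1:]):
            assert first == last + 1

    def test_too_many_segments_rejected(self):
        ang = AngularConformation(np.full(8, 1.0), np.zeros(7))
        with pytest.raises(ValueError):
            segment_decoy(ang, 9)


class TestFitting:
    def test_parameter_recovery_on_self_generated_decoy(self, two_segment_decoy):
        model, native = two_segment_decoy
        decoy = native.chain()
        nt = native.angles.n_theta
        fit = fit_model(decoy, [(1, nt // 2), (nt // 2 + 1, nt)], seed=0,
                        n_outer=40, target_rmsd=0.05)
        assert fit.rmsd_to_decoy < 0.1

    def test_best_so_far_trace_monotone(self, two_segment_decoy):
        model, native = two_segment_decoy
        decoy = native.chain()
        nt = native.angles.n_theta
        fit = fit_model(decoy, [(1, nt // 2), (nt // 2 + 1, nt)], seed=1, n_outer=10)
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert fit.rmsd_to_decoy <= trace[0]

    def test_fit_deterministic_given_seed(self, two_segment_decoy):
        _, native = two_segment_decoy
        decoy = native.chain()
        nt = native.angles.n_theta
        segm = [(1, nt // 2), (nt // 2 + 1, nt)]
        a = fit_model(decoy, segm, seed=5, n_outer=8)
        b = fit_model(decoy, segm, seed=5, n_outer=8)
        assert a.model == b.model
        assert a.rmsd_to_decoy == b.rmsd_to_decoy


class TestPinnedModel:
    def test_pinning_reproduces_decoy_geometry(self):
        from knotfold.fixtures import slipknot_toy

        chain = slipknot_toy()
        ang = coords_to_angles(chain)
        ang.bond_length = 3.8
        model = pinned_model(ang)
        ms = relax_to_critical_point(ang, model, tol=1e-6)
        assert rmsd_superposed(chain, ms.chain()) < 1.0
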