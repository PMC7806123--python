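"""Glauber / heat-bath Monte Carlo (un)folding engine.

Temperature-driven folding and unfolding are simulated as Markovian dynamics
in the internal coordinates.  Each step updates either one torsion angle
(Metropolis-free Glauber rule on a Gaussian proposal) or one bond angle
(direct heat-bath resampling from the conditional Boltzmann distribution at
an enhanced inverse temperature ``beta_hb = hb_ratio * beta`` -- bond angles
are far stiffer than torsions; the production ratio is 1e13).  A simulation
cycle runs three stages -- heating (beta shrinks geometrically),
thermalization (beta fixed), cooling (beta grows geometrically) -- starting
from the native multi-soliton, and a full ensemble repeats the cycle with
independent seeds.

Production-scale step counts (kept as named constants below) are 480e6
heating/cooling steps, 7e6 thermalization steps and 1000 cycles; tests and
the bundled experiments run heavily scaled-down schedules.

All stochastic operations consume a single named `numpy` Generator per
cycle; identical seeds give bit-identical trajectories.  The hot loop is
compiled with numba (:mod:`knotfold._mc_kernel`); a pure-Python twin of the
kernel is kept here both as documentation and as a cross-validation target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import logging

import numpy as np
import pandas as pd

from . import _mc_kernel as _k
from .energy import EnergyModel, angular_free_energy, delta_free_energy, has_hard_core_violation
from .frenet import AngularConformation, CAlphaChain, angles_to_coords, wrap_angle
from .observables import (
    EnsembleSummary,
    classify_final_state,
    radius_of_gyration,
    rmsd_superposed,
    torsion_fluctuation_profile,
)
from .solver import MultiSoliton

__all__ = [
    "Schedule",
    "MCState",
    "CycleResult",
    "glauber_acceptance_probability",
    "glauber_torsion_step",
    "heatbath_theta_step",
    "run_stage",
    "run_cycle",
    "run_ensemble",
    "HB_RATIO_PRODUCTION",
    "N_THERMALIZATION_PRODUCTION",
    "N_HEATING_PRODUCTION",
    "N_CYCLES_PRODUCTION",
]

HB_RATIO_PRODUCTION = 1e13
N_THERMALIZATION_PRODUCTION = 7_000_000
N_HEATING_PRODUCTION = 480_000_000
N_CYCLES_PRODUCTION = 1_000

log = logging.getLogger(__name__)

_CHUNK = 100_000          # steps between energy-drift audits
_DRIFT_TOL = 1e-6


@dataclass(frozen=True)
class Schedule:
    """Three-stage annealing schedule.

    ``beta`` is multiplied by the stage multiplier after every step:
    ``heating_multiplier < 1``, thermalization is pinned at 1, and
    ``cooling_multiplier > 1``.  ``record_stride`` controls how often
    observables (and coordinate/torsion snapshots) are recorded.
    """

    beta_start: float
    n_heating: int
    n_thermalization: int
    n_cooling: int
    heating_multiplier: float
    cooling_multiplier: float
    record_stride: int = 1_000
    theta_move_probability: float = 0.5
    hb_ratio: float = HB_RATIO_PRODUCTION
    n_theta_bins: int = 1024

    def __post_init__(self):
        if self.heating_multiplier <= 0 or self.cooling_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if not 0.0 <= self.theta_move_probability <= 1.0:
            raise ValueError("theta_move_probability must be in [0, 1]")

    @classmethod
    def from_beta_range(cls, beta_native: float, beta_hot: float,
                        n_heating: int, n_thermalization: int, n_cooling: int,
                        **kw) -> "Schedule":
        """Geometric schedule from the native (cold) beta down to ``beta_hot``
        and back; multipliers are derived from the step counts."""
        if beta_hot >= beta_native:
            raise ValueError("beta_hot must be below beta_native")
        hm = (beta_hot / beta_native) ** (1.0 / max(n_heating, 1))
        cm = (beta_native / beta_hot) ** (1.0 / max(n_cooling, 1))
        return cls(beta_native, n_heating, n_thermalization, n_cooling,
                   hm, cm, **kw)

    @property
    def total_steps(self) -> int:
        return self.n_heating + self.n_thermalization + self.n_cooling


@dataclass
class MCState:
    """Mutable Monte Carlo state: angles + cached coordinates + cached energy.

    The cached coordinates always equal ``angles_to_coords(angles)`` in the
    canonical gauge, and the cached (angular) free energy is audited against
    a full recomputation every 1e5 steps.
    """

    angles: AngularConformation
    model: EnergyModel
    beta: float
    rng: np.random.Generator
    hb_ratio: float = HB_RATIO_PRODUCTION
    chain: CAlphaChain = None
    energy: float = None
    n_accepted_phi: int = 0
    n_accepted_theta: int = 0

    def __post_init__(self):
        if self.chain is None:
            self.chain = angles_to_coords(self.angles)
        if self.energy is None:
            self.energy = angular_free_energy(self.angles, self.model)
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if has_hard_core_violation(self.chain, self.model.hard_core_radius,
                                   self.model.min_sequence_separation_for_core):
            raise ValueError("initial state violates the hard core")

    @classmethod
    def from_multisoliton(cls, native: MultiSoliton, beta: float, seed: int,
                          hb_ratio: float = HB_RATIO_PRODUCTION) -> "MCState":
        return cls(native.angles.copy(), native.model, beta,
                   np.random.default_rng(seed), hb_ratio)

    @property
    def beta_hb(self) -> float:
        return self.hb_ratio * self.beta

    def resync(self) -> None:
        """Recompute caches from the angles (used by the drift audit)."""
        self.chain = angles_to_coords(self.angles)
        self.energy = angular_free_energy(self.angles, self.model)


def glauber_acceptance_probability(delta_F: float, beta: float) -> float:
    """P = exp(-beta dF) / (1 + exp(-beta dF)); 1/2 at dF = 0."""
    x = beta * delta_F
    if x > 700.0:
        return 0.0
    if x < -700.0:
        return 1.0
    e = np.exp(-x)
    return float(e / (1.0 + e))


# ---------------------------------------------------------------------------
# single-step reference operations (public API, used directly in tests; the
# production loop runs the equivalent compiled kernel)

def glauber_torsion_step(state: MCState, site: int) -> bool:
    """One Glauber update of ``phi_site`` (1-based, ``2..n-2``).

    Proposal ``phi' = phi + (pi/2) R`` with R standard normal; acceptance
    requires both the Glauber draw and steric clearance (hard-core violating
    proposals are rejected outright, equivalent to dF = +inf).  Returns the
    acceptance flag; the state (angles, cached coordinates, cached energy)
    is updated in place on acceptance.
    """
    old = state.angles.phi[site - 2]
    new = float(wrap_angle(old + 0.5 * np.pi * state.rng.standard_normal()))
    dF = delta_free_energy(state.angles, state.model, site, "phi", new)
    # acceptance = Glauber draw AND steric clearance (independent events);
    # the draw is tested first so rejected proposals skip the rebuild
    if state.rng.random() >= glauber_acceptance_probability(dF, state.beta):
        return False
    state.angles.phi[site - 2] = new
    trial = angles_to_coords(state.angles)
    state.angles.phi[site - 2] = old
    if has_hard_core_violation(trial, state.model.hard_core_radius,
                               state.model.min_sequence_separation_for_core):
        return False
    state.angles.phi[site - 2] = new
    state.chain = trial
    state.energy += dF
    state.n_accepted_phi += 1
    return True


def heatbath_theta_step(state: MCState, site: int, n_bins: int = 1024) -> bool:
    """Heat-bath resampling of ``theta_site`` (1-based, ``1..n-2``).

    The new angle is drawn from ``P(theta) ~ exp(-beta_hb F_theta)`` on
    ``[0, pi)``, where ``F_theta`` collects every theta_site-dependent term
    of the free energy; the distribution is discretized on an ``n_bins``
    midpoint grid (inverse-CDF bin draw, uniform within the bin).  Draws
    that violate the hard core are rejected.  Returns True unless rejected.
    """
    th = state.angles.theta
    h = np.pi / n_bins
    x = (np.arange(n_bins) + 0.5) * h
    F = _theta_energy_profile(state.angles, state.model, site, x)
    logw = -state.beta_hb * (F - F.min())
    w = np.exp(logw)
    cdf = np.cumsum(w)
    target = state.rng.random() * cdf[-1]
    chosen = int(np.searchsorted(cdf, target, side="left"))
    chosen = min(chosen, n_bins - 1)
    new = (chosen + state.rng.random()) * h
    new = min(new, np.nextafter(np.pi, 0.0))
    old = th[site - 1]
    dF = delta_free_energy(state.angles, state.model, site, "theta", new)
    th[site - 1] = new
    trial = angles_to_coords(state.angles)
    if has_hard_core_violation(trial, state.model.hard_core_radius,
                               state.model.min_sequence_separation_for_core):
        th[site - 1] = old
        return False
    state.chain = trial
    state.energy += dF
    state.n_accepted_theta += 1
    return True


def _theta_energy_profile(angles: AngularConformation, model: EnergyModel,
                          site: int, x: np.ndarray) -> np.ndarray:
    """F_theta(x): every theta_site-dependent angular term, vectorized in x."""
    th, ph = angles.theta, angles.phi
    lam, m, a, b, c, d = model.site_parameters(angles)[:, site - 1]
    F = lam * (x**2 - m**2) ** 2
    j = site - 1
    if j > 0:
        F = F + (x - th[j - 1]) ** 2
    if j < th.size - 1:
        F = F + (th[j + 1] - x) ** 2
    if site >= 2:
        p = ph[site - 2]
        F = F + 0.5 * d * x**2 * p**2 - b * x**2 * p
    return F


# ---------------------------------------------------------------------------
# chunked stage driver

def _python_chunk(theta, phi, pos, params, beta0, multiplier, hb_ratio,
                  theta_prob, radius, min_sep, bond, n_bins, rand,
                  energy0, step_offset, record_stride, rec, rec_pos, rec_phi,
                  check_state):
    """Pure-Python twin of :func:`knotfold._mc_kernel.run_chunk`.

    Kept step-compatible with the compiled kernel (identical stream
    consumption and arithmetic); the test suite asserts bit-identical
    trajectories between the two.
    """
    n_steps = rand.shape[1]
    n_theta = theta.shape[0]
    n_phi = phi.shape[0]
    beta = beta0
    energy = energy0
    acc_phi = acc_th = 0
    h = np.pi / n_bins
    for step in range(n_steps):
        gstep = step_offset + step
        if record_stride > 0 and gstep % record_stride == 0:
            ridx = gstep // record_stride
            if ridx < rec.shape[0]:
                rec[ridx, 0] = beta
                rec[ridx, 1] = energy
                centred = pos - pos.mean(axis=0)
                rec[ridx, 2] = np.sqrt(np.mean(np.sum(centred**2, axis=1)))
                rec_pos[ridx] = pos
                rec_phi[ridx] = phi
        u_move, u_site, z, u_a, u_b = rand[:, step]
        if u_move >= theta_prob:
            s = min(2 + int(u_site * n_phi), n_phi + 1)
            old = phi[s - 2]
            new = _k._wrap.py_func(old + 0.5 * np.pi * z)
            dF = _delta_phi(theta, phi, params, s, new)
            x = beta * dF
            if x > 700.0:
                p_acc = 0.0
            elif x < -700.0:
                p_acc = 1.0
            else:
                e = np.exp(-x)
                p_acc = e / (1.0 + e)
            if u_a < p_acc:
                phi[s - 2] = new
                _k.rebuild_positions.py_func(theta, phi, bond, check_state)
                phi[s - 2] = old
                if not _k.hard_core_clash.py_func(check_state, radius, min_sep):
                    phi[s - 2] = new
                    energy += dF
                    pos[:] = check_state
                    acc_phi += 1
        else:
            s = min(1 + int(u_site * n_theta), n_theta)
            beta_hb = hb_ratio * beta
            xs = (np.arange(n_bins) + 0.5) * h
            F = np.array([_theta_local(theta, phi, params, s, xx) for xx in xs])
            arg = beta_hb * (F - F.min())
            w = np.where(arg > 746.0, 0.0, np.exp(-np.minimum(arg, 746.0)))
            cdf = np.cumsum(w)
            target = u_a * cdf[-1]
            chosen = n_bins - 1
            for mbin in range(n_bins):
                if cdf[mbin] >= target:
                    chosen = mbin
                    break
            new_theta = (chosen + u_b) * h
            if new_theta >= np.pi:
                new_theta = np.nextafter(np.pi, 0.0)
            old = theta[s - 1]
            dF = (_theta_local(theta, phi, params, s, new_theta)
                  - _theta_local(theta, phi, params, s, old))
            theta[s - 1] = new_theta
            _k.rebuild_positions.py_func(theta, phi, bond, check_state)
            if _k.hard_core_clash.py_func(check_state, radius, min_sep):
                theta[s - 1] = old
            else:
                energy += dF
                pos[:] = check_state
                acc_th += 1
        beta *= multiplier
    return beta, energy, acc_phi, acc_th


def _delta_phi(theta, phi, params, s, new):
    return _k._delta_phi_energy.py_func(theta, phi, params, s, new)


def _theta_local(theta, phi, params, s, x):
    return _k._theta_local_energy.py_func(theta, phi, params, s, x)


def run_stage(state: MCState, n_steps: int, multiplier: float,
              schedule: Schedule, step_offset: int = 0,
              rec=None, rec_pos=None, rec_phi=None,
              use_kernel: bool = True):
    """Drive one stage (fixed multiplier) for ``n_steps`` steps.

    Each step picks a uniformly random site and applies, with probability
    ``theta_move_probability``, a heat-bath bond-angle update, otherwise a
    Glauber torsion update; ``beta`` is multiplied by ``multiplier`` after
    every step.  Observables are written into the (optional) record arrays
    every ``schedule.record_stride`` steps, on the global step grid offset
    by ``step_offset``.  The cached energy is audited against a full
    recomputation every 1e5 steps.
    """
    params = state.model.site_parameters(state.angles)
    pos = state.chain.positions.copy()
    check = np.empty_like(pos)
    if rec is None:
        rec = np.empty((0, _k.NREC_FIELDS))
        rec_pos = np.empty((0, pos.shape[0], 3))
        rec_phi = np.empty((0, state.angles.n_phi))
    runner = _k.run_chunk if use_kernel else _python_chunk
    done = 0
    while done < n_steps:
        k = min(_CHUNK, n_steps - done)
        rand = np.empty((5, k))
        rand[0] = state.rng.random(k)
        rand[1] = state.rng.random(k)
        rand[2] = state.rng.standard_normal(k)
        rand[3] = state.rng.random(k)
        rand[4] = state.rng.random(k)
        beta, energy, a_phi, a_th = runner(
            state.angles.theta, state.angles.phi, pos, params,
            state.beta, multiplier, state.hb_ratio,
            schedule.theta_move_probability,
            state.model.hard_core_radius,
            state.model.min_sequence_separation_for_core,
            state.angles.bond_length, schedule.n_theta_bins, rand,
            state.energy, step_offset + done, schedule.record_stride,
            rec, rec_pos, rec_phi, check,
        )
        state.beta = float(beta)
        state.energy = float(energy)
        state.n_accepted_phi += int(a_phi)
        state.n_accepted_theta += int(a_th)
        done += k
        # energy-drift audit
        exact = angular_free_energy(state.angles, state.model)
        if abs(exact - state.energy) > _DRIFT_TOL * max(1.0, abs(exact)):
            raise RuntimeError(
                f"energy cache drift {abs(exact - state.energy):.3e} exceeds tolerance")
        state.energy = exact
    state.chain = CAlphaChain(pos)
    return state


@dataclass
class CycleResult:
    """One heating/thermalization/cooling cycle.

    ``records`` has one row per record-stride step: global step, stage,
    log10(beta), angular free energy, Rg, and RMSD to the native.
    ``phi_records`` holds the torsion snapshot per record (for fluctuation
    profiles).  ``final_class`` is set when classification was requested.
    """

    seed: int
    schedule: Schedule
    records: pd.DataFrame
    phi_records: np.ndarray
    pos_records: np.ndarray
    final_chain: CAlphaChain
    final_angles: AngularConformation
    final_class: Optional[str] = None
    final_report: object = None


def run_cycle(model: EnergyModel, native: MultiSoliton, schedule: Schedule,
              seed: int, classify: bool = True,
              rmsd_threshold: float = 2.0, use_kernel: bool = True,
              record_knots: bool = False) -> CycleResult:
    """Run one full cycle starting from the native multi-soliton.

    With ``record_knots`` every recorded frame is additionally typed by
    majority-vote closure (a ``knot`` column in ``records``); this is much
    more expensive than the default final-state-only screening.
    """
    state = MCState.from_multisoliton(native, schedule.beta_start, seed,
                                      hb_ratio=schedule.hb_ratio)
    native_chain = native.chain()
    total = schedule.total_steps
    stride = schedule.record_stride
    n_rec = total // stride + 1 if stride > 0 else 1
    n = state.chain.n
    rec = np.full((n_rec, _k.NREC_FIELDS), np.nan)
    rec_pos = np.zeros((n_rec, n, 3))
    rec_phi = np.zeros((n_rec, state.angles.n_phi))
    stages = [
        ("heating", schedule.n_heating, schedule.heating_multiplier),
        ("thermalization", schedule.n_thermalization, 1.0),
        ("cooling", schedule.n_cooling, schedule.cooling_multiplier),
    ]
    offset = 0
    stage_of_step = []
    for name, n_steps, mult in stages:
        if n_steps:
            log.info("cycle seed=%d: %s for %d steps (beta %.3g, multiplier %.6g)",
                     seed, name, n_steps, state.beta, mult)
            run_stage(state, n_steps, mult, schedule, offset,
                      rec, rec_pos, rec_phi, use_kernel=use_kernel)
        offset += n_steps
        stage_of_step.append((offset, name))
    # final record
    last = (total - 1) // stride + 1 if stride > 0 and total > 0 else 0
    if last < n_rec:
        rec[last, 0] = state.beta
        rec[last, 1] = state.energy
        rec[last, 2] = radius_of_gyration(state.chain)
        rec_pos[last] = state.chain.positions
        rec_phi[last] = state.angles.phi
    steps = np.arange(n_rec) * stride
    steps[-1] = total
    stage_names = []
    for srec in steps:
        for bound, name in stage_of_step:
            if srec < bound or bound == total:
                stage_names.append(name if srec < bound else stage_of_step[-1][1])
                break
    rmsd = np.array([
        rmsd_superposed(rec_pos[i], native_chain) if not np.isnan(rec[i, 0]) else np.nan
        for i in range(n_rec)
    ])
    records = pd.DataFrame({
        "step": steps,
        "stage": stage_names,
        "log10_beta": np.log10(rec[:, 0]),
        "energy": rec[:, 1],
        "rg": rec[:, 2],
        "rmsd": rmsd,
    })
    if record_knots:
        from .topology import vote_knot_type

        rng = np.random.default_rng(seed + 2**20)
        records["knot"] = [
            vote_knot_type(rec_pos[i], n_rays=5, rng=rng)[0]
            if not np.isnan(rec[i, 0]) else ""
            for i in range(n_rec)
        ]
    result = CycleResult(seed, schedule, records, rec_phi, rec_pos,
                         state.chain, state.angles.copy())
    if classify:
        from .topology import slipknot_scan

        report = slipknot_scan(state.chain, seed=seed)
        result.final_report = report
        result.final_class = classify_final_state(
            state.chain, native_chain, rmsd_threshold, knot_report=report)
    return result


def run_ensemble(model: EnergyModel, native: MultiSoliton, schedule: Schedule,
                 n_cycles: int, seed0: int = 0, classify: bool = True,
                 rmsd_threshold: float = 2.0,
                 use_kernel: bool = True) -> tuple:
    """Run ``n_cycles`` independent cycles (seeds ``seed0..seed0+n-1``).

    Returns ``(summary, cycles)`` where ``summary`` aggregates per-record
    mean/sd of Rg and RMSD, circular torsion-fluctuation profiles against
    the native, and the final-class fractions.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    cycles = [
        run_cycle(model, native, schedule, seed0 + i, classify=classify,
                  rmsd_threshold=rmsd_threshold, use_kernel=use_kernel)
        for i in range(n_cycles)
    ]
    rg = np.stack([c.records["rg"].to_numpy() for c in cycles])
    rmsd = np.stack([c.records["rmsd"].to_numpy() for c in cycles])
    log10b = cycles[0].records["log10_beta"].to_numpy()
    phis = np.stack([c.phi_records for c in cycles])  # (cycles, records, n_phi)
    dphi = np.empty(phis.shape[1:])
    spread = np.empty_like(dphi)
    for r in range(phis.shape[1]):
        dphi[r], spread[r] = torsion_fluctuation_profile(phis[:, r, :], native.angles.phi)
    sd_kw = dict(axis=0, ddof=1) if n_cycles > 1 else dict(axis=0)
    rg_sd = rg.std(**sd_kw) if n_cycles > 1 else np.full(rg.shape[1], np.nan)
    rmsd_sd = rmsd.std(**sd_kw) if n_cycles > 1 else np.full(rmsd.shape[1], np.nan)
    fractions: dict = {}
    if classify:
        labels = [c.final_class for c in cycles]
        for lab in labels:
            fractions[lab] = fractions.get(lab, 0) + 1
        fractions = {k: v / n_cycles for k, v in sorted(fractions.items())}
    summary = EnsembleSummary(
        log10_beta=log10b,
        rg_mean=rg.mean(axis=0), rg_sd=rg_sd,
        rmsd_mean=rmsd.mean(axis=0), rmsd_sd=rmsd_sd,
        delta_phi=dphi, delta_phi_spread=spread,
        class_fractions=fractions, n_cycles=n_cycles,
    )
    return summary, cycles
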