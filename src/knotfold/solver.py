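"""Multi-soliton critical points of the backbone free energy, and model fitting.

The folded state is modeled as the minimum-energy critical point of the
free energy: a multi-soliton profile of the generalized DNLS equations

    dF/dtheta_i = 2(2 theta_i - theta_{i+1} - theta_{i-1})
                  + 4 lambda_k (theta_i^2 - m_k^2) theta_i
                  + (d_k phi_i^2 - 2 b_k phi_i) theta_i            = 0
    dF/dphi_i   = (d_k theta_i^2 + c_k) phi_i - b_k theta_i^2 - a_k = 0

(interior sites; at the two boundary theta sites the missing-neighbour term
is dropped, consistent with the free-boundary pair term of the energy).  The
torsion equation is linear in phi and is solved in closed form each sweep;
theta is relaxed by bounded quasi-Newton descent.  Parameters are fitted so
that the relaxed multi-soliton reproduces a decoy C-alpha trace in the
Kabsch RMSD sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .frenet import AngularConformation, CAlphaChain, angles_to_coords, coords_to_angles, wrap_angle
from .energy import EnergyModel, SolitonSegment, angular_free_energy, free_energy, has_hard_core_violation
from .observables import rmsd_superposed

__all__ = [
    "MultiSoliton",
    "FitResult",
    "RelaxationError",
    "solve_phi_given_theta",
    "critical_point_residuals",
    "relax_to_critical_point",
    "pinned_model",
    "segment_decoy",
    "fit_model",
]

log = logging.getLogger(__name__)

_THETA_MAX = np.nextafter(np.pi, 0.0)


class RelaxationError(RuntimeError):
    """Relaxation failed to reach the residual tolerance."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class MultiSoliton:
    """An angular conformation certified as a critical point of a model."""

    angles: AngularConformation
    model: EnergyModel
    residual_norm: float
    energy: float

    def chain(self, seed_frame=None) -> CAlphaChain:
        return angles_to_coords(self.angles, seed_frame)


@dataclass
class FitResult:
    model: EnergyModel
    multisoliton: MultiSoliton
    rmsd_to_decoy: float
    trace: list = field(default_factory=list)  # best-so-far RMSD per outer iteration


def solve_phi_given_theta(theta, segment: SolitonSegment):
    """Closed-form torsion stationarity: phi = (b theta^2 + a)/(d theta^2 + c),
    wrapped to [-pi, pi)."""
    theta = np.asarray(theta, dtype=float)
    denom = segment.d * theta**2 + segment.c
    return wrap_angle((segment.b * theta**2 + segment.a) / denom)


def critical_point_residuals(angles: AngularConformation, model: EnergyModel):
    """Exact gradient of the angular free energy, split per equation.

    Returns ``(r_theta, r_phi)`` with ``r_theta[i-1] = dF/dtheta_i`` and
    ``r_phi[i-2] = dF/dphi_i`` (1-based sites).  Zero residuals certify a
    multi-soliton.
    """
    th, ph = angles.theta, angles.phi
    lam, m, a, b, c, d = model.site_parameters(angles)
    r_th = 4.0 * lam * (th**2 - m**2) * th
    # free-boundary discrete Laplacian
    r_th[:-1] += 2.0 * (th[:-1] - th[1:])
    r_th[1:] += 2.0 * (th[1:] - th[:-1])
    # torsion coupling exists where phi exists (sites 2..n-2)
    r_th[1:] += (d[1:] * ph**2 - 2.0 * b[1:] * ph) * th[1:]
    r_ph = (d[1:] * th[1:] ** 2 + c[1:]) * ph - b[1:] * th[1:] ** 2 - a[1:]
    return r_th, r_ph


def _residual_norm(angles, model) -> float:
    r_th, r_ph = critical_point_residuals(angles, model)
    return float(max(np.abs(r_th).max(), np.abs(r_ph).max(initial=0.0)))


def _newton_polish(angles: AngularConformation, model: EnergyModel):
    """Hybrid-Powell root of the residual system from the given state.

    Returns the candidate conformation, or None if the root search failed
    or left the admissible angle ranges.
    """
    from scipy.optimize import root

    nt = angles.n_theta

    def grad(x):
        st = AngularConformation(np.clip(x[:nt], 0.0, _THETA_MAX),
                                 wrap_angle(x[nt:]), angles.bond_length)
        r_th, r_ph = critical_point_residuals(st, model)
        return np.concatenate([r_th, r_ph])

    x0 = np.concatenate([angles.theta, angles.phi])
    sol = root(grad, x0, method="hybr", tol=1e-13)
    xt = sol.x[:nt]
    if (sol.success and np.all(xt >= 0.0) and np.all(xt < np.pi)
            and np.all(np.abs(sol.x[nt:]) <= np.pi + 1e-9)):
        return AngularConformation(np.clip(xt, 0.0, _THETA_MAX),
                                   wrap_angle(sol.x[nt:]), angles.bond_length)
    return None


def relax_to_critical_point(initial: AngularConformation, model: EnergyModel,
                            tol: float = 1e-9, max_iter: int = 200) -> MultiSoliton:
    """Alternating minimization to a critical point.

    Each sweep solves the torsion equation in closed form and then lowers the
    energy over theta with bounded L-BFGS; the energy is non-increasing along
    the sweeps.  Raises :class:`RelaxationError` if the residual norm does not
    reach ``tol`` within ``max_iter`` sweeps, or if the relaxed chain violates
    the hard core.
    """
    angles = initial.copy()
    lam, m, a, b, c, d = model.site_parameters(angles)
    trace = [_residual_norm(angles, model)]
    if trace[0] < tol:
        F, clash = free_energy(angles, model)
        if clash:
            raise RelaxationError("initial critical point violates the hard core", trace)
        return MultiSoliton(angles, model, trace[0], F)

    def _local_fallback(error):
        # the descent phases may hop to a distant (possibly sterically
        # excluded) basin; as a fallback, Newton from the original
        # initialization converges to a critical point near it
        local = _newton_polish(initial, model)
        if local is not None and _residual_norm(local, model) < tol:
            F_loc, clash_loc = free_energy(local, model)
            if not clash_loc:
                return MultiSoliton(local, model, _residual_norm(local, model), F_loc)
        raise error

    def F_of_theta(th, ph):
        e = np.sum((th[1:] - th[:-1]) ** 2) + np.sum(lam * (th**2 - m**2) ** 2)
        t2 = th[1:] ** 2
        e += np.sum(0.5 * d[1:] * t2 * ph**2 - b[1:] * t2 * ph)
        return e

    def grad_theta(th, ph):
        g = 4.0 * lam * (th**2 - m**2) * th
        g[:-1] += 2.0 * (th[:-1] - th[1:])
        g[1:] += 2.0 * (th[1:] - th[:-1])
        g[1:] += (d[1:] * ph**2 - 2.0 * b[1:] * ph) * th[1:]
        return g

    bounds = [(0.0, _THETA_MAX)] * angles.n_theta
    n_sweeps = min(max_iter, 30)
    for sweep in range(n_sweeps):
        # exact torsion minimization (unique when d*theta^2 + c > 0)
        denom = d[1:] * angles.theta[1:] ** 2 + c[1:]
        angles.phi = wrap_angle((b[1:] * angles.theta[1:] ** 2 + a[1:]) / denom)
        res = minimize(
            F_of_theta, angles.theta, args=(angles.phi,), jac=grad_theta,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 0.1 * tol},
        )
        angles.theta = np.clip(res.x, 0.0, _THETA_MAX)
        trace.append(_residual_norm(angles, model))
        if trace[-1] < tol:
            break
    if trace[-1] >= tol:
        # the alternating scheme converges only linearly when the theta-phi
        # coupling (b, d) is strong; finish with a joint quasi-Newton descent
        # of F over (theta, phi) -- its gradient is exactly the residual
        nt = angles.n_theta

        def F_joint(x):
            st = AngularConformation(np.clip(x[:nt], 0.0, _THETA_MAX),
                                     wrap_angle(x[nt:]), angles.bond_length)
            return angular_free_energy(st, model)

        def grad_joint(x):
            st = AngularConformation(np.clip(x[:nt], 0.0, _THETA_MAX),
                                     wrap_angle(x[nt:]), angles.bond_length)
            r_th, r_ph = critical_point_residuals(st, model)
            return np.concatenate([r_th, r_ph])

        x0 = np.concatenate([angles.theta, angles.phi])
        jb = bounds + [(-np.pi, np.nextafter(np.pi, 0.0))] * angles.n_phi
        res = minimize(F_joint, x0, jac=grad_joint, method="L-BFGS-B",
                       bounds=jb,
                       options={"maxiter": 20 * max_iter, "ftol": 1e-18,
                                "gtol": 0.05 * tol})
        angles.theta = np.clip(res.x[:nt], 0.0, _THETA_MAX)
        angles.phi = wrap_angle(res.x[nt:])
        trace.append(_residual_norm(angles, model))
    if trace[-1] >= tol:
        # descent is limited by machine precision on F near a shallow
        # minimum; polish by Newton root-finding on the residual system,
        # which converges in the gradient rather than in F
        cand = _newton_polish(angles, model)
        if cand is not None and _residual_norm(cand, model) < trace[-1]:
            angles = cand
        trace.append(_residual_norm(angles, model))
    if trace[-1] >= tol:
        return _local_fallback(RelaxationError(
            f"no convergence after {max_iter} sweeps (residual {trace[-1]:.3e})", trace))
    F, clash = free_energy(angles, model)
    if clash:
        return _local_fallback(RelaxationError(
            "relaxed critical point violates the hard core", trace))
    return MultiSoliton(angles, model, trace[-1], F)


# ---------------------------------------------------------------------------
# segmentation

def segment_decoy(angles: AngularConformation, n_segments: int):
    """Partition residues 1..n_theta into soliton segments.

    Solitons sit on loops, where the bond-angle profile makes an excursion
    away from its regular (helix/strand) baseline.  The heuristic scores each
    interior site by the smoothed absolute deviation of theta from its local
    median and cuts at the ``n_segments - 1`` most prominent excursion
    centers, so a helix-loop-helix decoy is cut inside its loop.

    Returns a list of ``(first_residue, last_residue)`` 1-based inclusive
    ranges exactly partitioning ``[1, n_theta]``.
    """
    n = angles.n_theta
    if n_segments < 1 or n_segments > n:
        raise ValueError("n_segments must be in [1, n_theta]")
    if n_segments == 1:
        return [(1, n)]
    th = angles.theta
    med = float(np.median(th))
    dev = np.abs(th - med)
    k = np.ones(3) / 3.0
    score = np.convolve(dev, k, mode="same")
    # greedy pick of excursion centers, enforcing a minimum spacing so the
    # cuts can define non-empty segments
    order = np.argsort(score)[::-1]
    min_gap = max(2, n // (3 * n_segments))
    cuts: list[int] = []
    for idx in order:
        site = int(idx) + 1
        if site <= 1 or site >= n:
            continue
        if all(abs(site - cps) >= min_gap for cps in cuts):
            cuts.append(site)
        if len(cuts) == n_segments - 1:
            break
    if len(cuts) < n_segments - 1:  # degenerate profile: fall back to even split
        cuts = [round(j * n / n_segments) + 1 for j in range(1, n_segments)]
    cuts = sorted(set(cuts))
    bounds = [1] + cuts + [n + 1]
    return [(bounds[j], bounds[j + 1] - 1) for j in range(len(bounds) - 1)]


def pinned_model(angles: AngularConformation, lam: float = 40.0,
                 c=1.0) -> EnergyModel:
    """Site-resolved model whose multi-soliton reproduces ``angles``.

    The finest admissible segmentation -- one segment per bond-angle site --
    with parameters obtained in closed form: ``a_i = c phi_i`` makes the
    decoy torsions exactly stationary (b = d = 0), and the quartic centre
    ``m_i`` inverts the bond-angle stationarity including the discrete
    Laplacian of the decoy profile.  With a stiff quartic (large ``lam``)
    the resulting critical point tracks the decoy to a fraction of an
    Angstrom, which makes this the standard way to turn an arbitrary
    geometric fixture into a Monte Carlo native state.  (Fitted coarse
    segmentations, in contrast, only stay near protein-like decoys whose
    angle profiles are piecewise regular.)
    """
    nt = angles.n_theta
    th = angles.theta
    c_arr = np.broadcast_to(np.asarray(c, dtype=float), (nt,))
    segs = []
    for i in range(1, nt + 1):
        j = i - 1
        t0 = th[j]
        ci = float(c_arr[j])
        a = ci * angles.phi[i - 2] if i >= 2 else 0.0
        lap = 0.0
        if j > 0:
            lap += 2.0 * (t0 - th[j - 1])
        if j < nt - 1:
            lap += 2.0 * (t0 - th[j + 1])
        # the inversion is clamped near theta = 0, where it is ill-conditioned
        m2 = t0 * t0 + lap / (4.0 * lam * max(t0, 0.15))
        segs.append(SolitonSegment(i, i, lam, float(np.sqrt(max(m2, 1e-4))),
                                   a, 0.0, ci, 0.0))
    return EnergyModel(segs)


# ---------------------------------------------------------------------------
# fitting

def _init_segment(angles: AngularConformation, first: int, last: int,
                  lam: float = 4.0, chiral_only: bool = False) -> SolitonSegment:
    """Moment-matching initialization of one segment from the decoy's angles.

    With c fixed to 1 (the torsion equation is scale degenerate), the
    stationarity phi = (b theta^2 + a)/(d theta^2 + c) is linear in (a, b, d)
    and fitted by least squares: a + b theta^2 - d theta^2 phi = phi.  The
    quartic centre m is then recovered by inverting the theta stationarity
    site by site -- m_i^2 = theta_i^2 + (laplacian + coupling)/(4 lam
    theta_i) -- and taking the segment median, so the decoy profile is
    already close to a critical point of the initial model.
    """
    nt = angles.n_theta
    th = angles.theta[first - 1:last]
    # phi sites within the segment (phi site i -> array index i-2)
    plo, phi_hi = max(first, 2) - 2, min(last, nt) - 1
    a = b = d = 0.0
    if chiral_only and phi_hi > plo:
        # helicity-only coupling: a = c * mean phi, b = d = 0 -- robust when
        # the full regression is dominated by coordinate noise
        a = float(np.mean(angles.phi[plo:phi_hi]))
    elif phi_hi > plo:
        ph = angles.phi[plo:phi_hi]
        t2 = angles.theta[plo + 1:phi_hi + 1] ** 2
        A = np.c_[np.ones_like(ph), t2, -t2 * ph]
        # tiny ridge on (b, d) so degenerate profiles (e.g. an ideal helix,
        # where the design rows coincide) resolve to the pure-helicity
        # solution a = c*phi, b = d = 0
        eps = np.sqrt(1e-10 * max(ph.size, 1))
        A_reg = np.vstack([A, [[0.0, eps, 0.0], [0.0, 0.0, eps]]])
        y_reg = np.concatenate([ph, [0.0, 0.0]])
        coef, *_ = np.linalg.lstsq(A_reg, y_reg, rcond=None)
        a, b, d = (float(x) for x in coef)
        if d * np.pi**2 + 1.0 <= 0.05:  # keep the denominator safely positive
            d = (0.05 - 1.0) / np.pi**2
    ms = []
    for i in range(first, last + 1):
        j = i - 1
        t0 = angles.theta[j]
        if t0 < 0.15:  # inversion ill-conditioned near theta = 0
            continue
        lap = 0.0
        if j > 0:
            lap += 2.0 * (t0 - angles.theta[j - 1])
        if j < nt - 1:
            lap += 2.0 * (t0 - angles.theta[j + 1])
        coup = 0.0
        if i >= 2:
            p = angles.phi[i - 2]
            coup = (d * p * p - 2.0 * b * p) * t0
        m2 = t0 * t0 + (lap + coup) / (4.0 * lam * t0)
        if m2 > 0.0:
            ms.append(np.sqrt(m2))
    if ms:
        m = float(np.median(ms))
    else:
        m = max(float(np.sqrt(np.mean(th**2))) if th.size else 1.0, 0.3)
    return SolitonSegment(first, last, lam, m, a, b, 1.0, d)


def _perturb_model(model: EnergyModel, rng: np.random.Generator, scale: float) -> EnergyModel:
    segs = []
    for s in model.segments:
        for _ in range(40):
            try:
                segs.append(SolitonSegment(
                    s.first_residue, s.last_residue,
                    abs(s.lambda_ * np.exp(scale * rng.normal())),
                    abs(s.m + 0.3 * scale * rng.normal()),
                    s.a + 0.3 * scale * rng.normal(),
                    s.b + 0.3 * scale * rng.normal(),
                    s.c,
                    s.d + 0.3 * scale * rng.normal(),
                ))
                break
            except ValueError:
                continue
        else:
            segs.append(s)
    return EnergyModel(segs, model.hard_core_radius,
                       model.min_sequence_separation_for_core)


def fit_model(decoy: CAlphaChain, segmentation, seed: int = 0,
              n_outer: int = 60, relax_tol: float = 1e-8,
              target_rmsd: float | None = None) -> FitResult:
    """Fit segment parameters so the relaxed multi-soliton matches a decoy.

    ``segmentation`` is either an integer (number of segments; boundaries
    chosen by :func:`segment_decoy`) or an explicit list of
    ``(first, last)`` ranges.  The outer loop is a seeded stochastic
    hill-climb (Gaussian parameter perturbations with an annealed step size)
    around a regression-based initial guess; the inner loop relaxes the decoy
    angles to the nearest critical point.  The objective is the Kabsch RMSD
    between the decoy and the relaxed multi-soliton.  ``target_rmsd`` allows
    early stopping.
    """
    rng = np.random.default_rng(seed)
    dec_angles = coords_to_angles(decoy)
    dec_angles.bond_length = 3.8  # model-side chains live at the canonical bond length
    if isinstance(segmentation, (int, np.integer)):
        segmentation = segment_decoy(dec_angles, int(segmentation))

    def evaluate(candidate: EnergyModel):
        try:
            ms = relax_to_critical_point(dec_angles, candidate, tol=relax_tol)
        except RelaxationError as err:
            log.debug("candidate discarded: %s", err)
            return None, np.inf
        return ms, rmsd_superposed(decoy, ms.chain())

    # moment-matched initialization; if its relaxation fails (noisy or
    # degenerate torsion regression), fall back to the helicity-only form
    best_ms, best_rmsd, best_model = None, np.inf, None
    for chiral_only in (False, True):
        model = EnergyModel([_init_segment(dec_angles, f, l,
                                           chiral_only=chiral_only)
                             for f, l in segmentation])
        ms, rmsd = evaluate(model)
        if rmsd < best_rmsd:
            best_ms, best_rmsd, best_model = ms, rmsd, model
        if best_ms is not None:
            break
    trace = [best_rmsd]
    for it in range(n_outer):
        if best_rmsd <= (target_rmsd if target_rmsd is not None else 0.0):
            break
        scale = 0.5 * 0.95**it
        cand = _perturb_model(best_model, rng, scale)
        ms, rmsd = evaluate(cand)
        if rmsd < best_rmsd:
            best_model, best_ms, best_rmsd = cand, ms, rmsd
        trace.append(best_rmsd)
    if best_ms is None:
        raise RelaxationError("no candidate model produced a valid multi-soliton", trace)
    return FitResult(best_model, best_ms, float(best_rmsd), trace)
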