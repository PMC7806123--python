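"""Deterministic synthetic test structures.

Every fixture is reproducible bit-for-bit from its parameters (and seed,
where one applies).  Angle-defined fixtures (helix, strand, straight,
random) are built through the exact reconstruction, so their bond lengths
are exactly 3.8 Angstrom; curve-defined fixtures (torus knots, the toy
slipknot) are resampled to a 3.8 Angstrom mean spacing.

The regular secondary-structure fixtures use the canonical internal
coordinates of the model: a right-handed alpha-helix has
``(theta, phi) ~ (pi/2, 1)`` and a beta-strand ``(theta, phi) ~ (1, pi)``.
"""

from __future__ import annotations

import numpy as np

from .frenet import BOND_LENGTH, AngularConformation, CAlphaChain, angles_to_coords, wrap_angle
from .energy import EnergyModel, SolitonSegment

__all__ = [
    "ALPHA_HELIX_ANGLES",
    "BETA_STRAND_ANGLES",
    "helix_chain",
    "strand_chain",
    "straight_chain",
    "random_chain",
    "torus_knot",
    "slipknot_toy",
    "toy_two_segment_model",
    "generate_fixture",
]

ALPHA_HELIX_ANGLES = (np.pi / 2, 1.0)
BETA_STRAND_ANGLES = (1.0, np.pi)


def _constant_angle_chain(n: int, theta: float, phi: float) -> tuple:
    angles = AngularConformation(
        np.full(n - 2, theta), np.full(n - 3, wrap_angle(phi)), BOND_LENGTH
    )
    return angles_to_coords(angles), angles


def helix_chain(n: int = 20):
    """Ideal right-handed alpha-helix, ``(theta, phi) = (pi/2, 1)``.

    Returns ``(chain, angles)``.
    """
    return _constant_angle_chain(n, *ALPHA_HELIX_ANGLES)


def strand_chain(n: int = 20):
    """Ideal beta-strand, ``(theta, phi) = (1, pi)`` (phi stored as -pi,
    the same angle wrapped to [-pi, pi))."""
    return _constant_angle_chain(n, *BETA_STRAND_ANGLES)


def straight_chain(n: int = 10) -> CAlphaChain:
    """Collinear chain at 3.8 Angstrom spacing (degenerate Frenet geometry)."""
    pos = np.zeros((n, 3))
    pos[:, 2] = BOND_LENGTH * np.arange(n)
    return CAlphaChain(pos)


def random_chain(n: int = 50, seed: int = 0,
                 theta_range=(0.25, 2.8), phi_range=(-3.0, 3.0)):
    """Non-degenerate random chain drawn in angle space.

    Angles stay away from the degenerate theta = 0, pi rays, so frames are
    well defined everywhere.  Returns ``(chain, angles)``.
    """
    rng = np.random.default_rng(seed)
    angles = AngularConformation(
        rng.uniform(*theta_range, n - 2), rng.uniform(*phi_range, n - 3), BOND_LENGTH
    )
    return angles_to_coords(angles), angles


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed curve polyline to n equally spaced vertices."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for k, t in enumerate(targets):
        i = int(np.searchsorted(s, t, side="right")) - 1
        f = (t - s[i]) / seg[i]
        out[k] = closed[i] + f * (closed[i + 1] - closed[i])
    return out


def torus_knot(p: int = 2, q: int = 3, n: int = 120, closed: bool = True,
               R: float = 12.0, r: float = 5.0) -> np.ndarray:
    """(p, q) torus knot sampled as a polygon and rescaled to 3.8 Angstrom
    mean spacing.  (2, 3) is the trefoil; (4_1 is not a torus knot -- see
    :func:`figure_eight`.)  Returns an ``(n, 3)`` vertex array; when
    ``closed`` the last vertex connects back to the first, otherwise the
    array is an open chain.
    """
    if np.gcd(p, q) != 1 or p < 2 or q < 2:
        raise ValueError(f"({p}, {q}) does not define a torus knot")
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.c_[(R + r * np.cos(q * t)) * np.cos(p * t),
                (R + r * np.cos(q * t)) * np.sin(p * t),
                r * np.sin(q * t)]
    pts = _resample_closed(pts, n)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    pts *= BOND_LENGTH / seg.mean()
    return pts if closed else pts[:-1]


def figure_eight(n: int = 160, closed: bool = True) -> np.ndarray:
    """Figure-eight knot 4_1 from its standard parametrization, rescaled to
    3.8 Angstrom mean spacing."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.c_[(2 + np.cos(2 * t)) * np.cos(3 * t),
                (2 + np.cos(2 * t)) * np.sin(3 * t),
                np.sin(4 * t)]
    pts = _resample_closed(pts, n)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    pts *= BOND_LENGTH / seg.mean()
    return pts if closed else pts[:-1]


def _resample_open(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    targets = np.linspace(0.0, s[-1], n)
    res = np.empty((n, 3))
    for k, tt in enumerate(targets):
        i = min(int(np.searchsorted(s, tt, side="right")) - 1, len(seg) - 1)
        f = (tt - s[i]) / seg[i]
        res[k] = pts[i] + f * (pts[i + 1] - pts[i])
    return res


def _inflate(pts: np.ndarray, d_target: float, bond: float = BOND_LENGTH,
             max_iter: int = 2000, push: float = 0.25,
             stop_at: float | None = None) -> np.ndarray:
    """Open up steric clearance while preserving topology.

    Deterministically pushes apart every pair at sequence separation >= 2
    closer than ``d_target`` and re-imposes exact bond lengths by SHAKE-style
    projection.  The per-iteration displacements are small compared to the
    clearance, so the isotopy class of the chain is not changed.
    """
    pts = pts.copy()
    n = len(pts)
    ii, jj = np.triu_indices(n, k=2)
    for _ in range(max_iter):
        diff = pts[ii] - pts[jj]
        d = np.linalg.norm(diff, axis=1)
        close = d < d_target
        if (stop_at is not None and d.min() >= stop_at) or not np.any(close):
            break
        u = diff[close] / d[close, None]
        f = push * (d_target - d[close]) / 2.0
        disp = np.zeros_like(pts)
        np.add.at(disp, ii[close], f[:, None] * u)
        np.add.at(disp, jj[close], -f[:, None] * u)
        pts += disp
        for _ in range(10):
            vec = np.diff(pts, axis=0)
            L = np.linalg.norm(vec, axis=1)
            corr = 0.5 * ((L - bond) / L)[:, None] * vec
            pts[:-1] += corr
            pts[1:] -= corr
    for _ in range(80):  # polish bonds to machine precision
        vec = np.diff(pts, axis=0)
        L = np.linalg.norm(vec, axis=1)
        corr = 0.5 * ((L - bond) / L)[:, None] * vec
        pts[:-1] += corr
        pts[1:] -= corr
    return pts


def slipknot_toy(n: int = 64, clearance: float = 4.3) -> CAlphaChain:
    """Threaded-hairpin slipknot chain.

    The head of the chain traces a full overhand knot (an open trefoil whose
    final stretch dives radially inward and threads through the knotting
    loop); the tail then hairpins back alongside the curve and retreats out
    of the loop.  Subchains ending inside the threaded stretch are trefoils
    under closure, while the whole chain is unknotted -- the defining
    geometry of a slipknot.  A deterministic inflation step opens steric
    clearance above the 3.8 Angstrom hard core while preserving the isotopy
    class, so the fixture is directly usable as a Monte Carlo native state.

    Returns an open :class:`CAlphaChain` with exactly 3.8 Angstrom bonds.
    """
    R_t, r_t = 12.0, 5.0
    t0, t1 = 0.35, 2.0 * np.pi + 0.3
    ramp_start = 2.0 * np.pi - 0.4
    r_in, off, back_end = 1.2, 6.0, 3.0

    def curve(t, rr):
        return np.c_[(R_t + rr * np.cos(3 * t)) * np.cos(2 * t),
                     (R_t + rr * np.cos(3 * t)) * np.sin(2 * t),
                     rr * np.sin(3 * t)]

    t = np.linspace(t0, t1, 48)
    rr_head = np.where(
        t < ramp_start, r_t,
        r_t + (r_in - r_t) * np.clip((t - ramp_start) / (t1 - ramp_start), 0.0, 1.0))
    head = curve(t, rr_head)
    back = np.linspace(t1 - 0.25, back_end, 34)
    rr_tail = np.empty_like(back)
    overlap = back >= ramp_start
    rr_tail[overlap] = r_in + 1.4
    fade = np.clip((ramp_start - back[~overlap]) / 1.0, 0.0, 1.0)
    rr_tail[~overlap] = (r_in + 1.4) + fade * ((r_t + off) - (r_in + 1.4))
    tail = curve(back, rr_tail)
    pts = _resample_open(np.vstack([head, tail]), n)
    pts *= BOND_LENGTH / np.linalg.norm(np.diff(pts, axis=0), axis=1).mean()
    pts = _inflate(pts, d_target=clearance, stop_at=clearance - 0.25)
    return CAlphaChain(pts)


def toy_two_segment_model(n: int = 24) -> EnergyModel:
    """A known two-segment energy model for parameter-recovery experiments.

    Segment 1 favours a helix-like profile, segment 2 a strand-like one,
    with mild chiral couplings; its relaxed multi-soliton is a compact but
    clash-free two-motif "protein".
    """
    half = (n - 2) // 2
    return EnergyModel([
        SolitonSegment(1, half, lambda_=3.0, m=np.pi / 2, a=0.4, b=0.25, c=1.0, d=0.3),
        SolitonSegment(half + 1, n, lambda_=2.0, m=1.0, a=0.8, b=0.6, c=0.8, d=0.1),
    ])


_toy_system_cache: dict = {}


def toy_slipknot_system(n: int = 64, lam: float = 40.0):
    """The slipknot study system: chain + pinning model + native multi-soliton.

    Builds the threaded-hairpin chain and attaches the site-resolved pinning
    model with a staged torsion-stiffness profile: the threading stretch of
    the knotting loop (sites ``0.355..0.68`` of the chain) carries deep
    torsion wells (c = 6) so the correct threading geometry locks in early
    during cooling, the threaded tail carries shallow wells (c = 0.5) so it
    resolves last and can still slide out of the loop, and the rest of the
    chain sits at c = 1.  This staging is what makes slipknot refolding
    observable at scaled-down schedule lengths; real slipknotted proteins
    realize the same ordering through the relative stability of their
    secondary-structure elements.

    Returns ``(chain, model, multisoliton)``; the multi-soliton is
    slipknotted, clash-free, and within ~0.6 Angstrom of the geometric
    fixture.  Results are cached per ``(n, lam)``.
    """
    key = (n, lam)
    if key not in _toy_system_cache:
        from .solver import pinned_model, relax_to_critical_point
        from .frenet import coords_to_angles

        chain = slipknot_toy(n)
        angles = coords_to_angles(chain)
        angles.bond_length = BOND_LENGTH
        nt = angles.n_theta
        sites = np.arange(1, nt + 1)
        c = np.ones(nt)
        lo, hi = round(0.355 * nt), round(0.68 * nt)
        c[(sites >= lo) & (sites <= hi)] = 6.0
        c[sites > hi] = 0.5
        model = pinned_model(angles, lam=lam, c=c)
        native = relax_to_critical_point(angles, model, tol=1e-6)
        _toy_system_cache[key] = (chain, model, native)
    return _toy_system_cache[key]


def slipknot_trend_schedules():
    """Slow- and fast-cooling schedules for the toy slipknot system.

    Both sweep ``beta`` geometrically between 3000 (cold: thermal positional
    noise well below the native-classification threshold) and 0.1 (hot: the
    chain is a self-avoiding random coil), with 20e3 heating and 5e3
    thermalization steps.  They differ in the cooling rate: 150e3 steps
    (slow) versus 5e3 steps (fast).  Returns ``(slow, fast)``.
    """
    from .mc import Schedule

    common = dict(n_heating=20_000, n_thermalization=5_000,
                  record_stride=0, n_theta_bins=256)
    slow = Schedule.from_beta_range(3000.0, 0.1, n_cooling=150_000, **common)
    fast = Schedule.from_beta_range(3000.0, 0.1, n_cooling=5_000, **common)
    return slow, fast


def generate_fixture(kind: str, n: int | None = None, seed: int = 0, **kw):
    """Uniform entry point used by the command line.

    ``kind`` is one of ``helix | strand | straight | random | torus_knot |
    figure_eight | slipknot_toy``.  Returns a :class:`CAlphaChain` (angles,
    where defined, can be recovered with
    :func:`~knotfold.frenet.coords_to_angles`).
    """
    if kind == "helix":
        return helix_chain(n or 20)[0]
    if kind == "strand":
        return strand_chain(n or 20)[0]
    if kind == "straight":
        return straight_chain(n or 10)
    if kind == "random":
        return random_chain(n or 50, seed=seed)[0]
    if kind == "torus_knot":
        return CAlphaChain(torus_knot(kw.get("p", 2), kw.get("q", 3), n or 120,
                                      closed=False))
    if kind == "figure_eight":
        return CAlphaChain(figure_eight(n or 160, closed=False))
    if kind == "slipknot_toy":
        return slipknot_toy(n or 40)
    raise ValueError(f"unknown fixture kind {kind!r}")
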