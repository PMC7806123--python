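"""Mechanical free energy of the backbone: per-segment DNLS terms + hard core.

The backbone free energy is a generalized discrete nonlinear Schrodinger
(DNLS) energy in the internal coordinates ``(theta_i, phi_i)``.  The chain is
partitioned into soliton segments, each carrying six constant parameters
``(lambda, m, a, b, c, d)``; within segment ``k`` the angular part of the
energy reads

    F_ang = sum_pairs (theta_{i+1} - theta_i)^2
          + sum_i [ lambda_k (theta_i^2 - m_k^2)^2
                    + (d_k/2) theta_i^2 phi_i^2 + (c_k/2) phi_i^2
                    - b_k theta_i^2 phi_i - a_k phi_i ]

The nearest-neighbour pair term is the DNLS discrete Laplacian written in
free-boundary (difference) form; in the bulk it is identical to the
``-2 theta_{i+1} theta_i + 2 theta_i^2`` form (the difference telescopes to
boundary terms) and it makes the uniform profile ``theta = m`` an exact
critical point of a single segment.  The ``c`` term is a Proca mass, and the
``a``/``b`` terms (DNLS conserved helicity and momentum) break parity and
make the backbone right-handed chiral for positive values.

Long-range interactions enter only through a hard-core Pauli repulsion: any
two C-alpha atoms at sequence separation >= 2 must stay at least 3.8 Angstrom
apart.  The hard core is enforced as a move-rejection constraint (a flag
here, acceptance probability zero in the Monte Carlo engine), never as a
finite energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .frenet import AngularConformation, CAlphaChain, angles_to_coords

__all__ = [
    "SolitonSegment",
    "EnergyModel",
    "free_energy",
    "angular_free_energy",
    "delta_free_energy",
    "hard_core_violations",
    "has_hard_core_violation",
    "write_parameter_file",
    "read_parameter_file",
]

HARD_CORE_RADIUS = 3.8
"""Default excluded-volume radius, Angstrom (== the virtual bond length)."""

MIN_CORE_SEPARATION = 2
"""Smallest |i-j| checked by the hard core; bonded neighbours are exempt."""


@dataclass(frozen=True)
class SolitonSegment:
    """One soliton segment: a 1-based inclusive residue range plus the six
    DNLS parameters that are constant along it."""

    first_residue: int
    last_residue: int
    lambda_: float
    m: float
    a: float = 0.0
    b: float = 0.0
    c: float = 1.0
    d: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "first_residue", int(self.first_residue))
        object.__setattr__(self, "last_residue", int(self.last_residue))
        for f in ("lambda_", "m", "a", "b", "c", "d"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if self.first_residue > self.last_residue:
            raise ValueError("first_residue must be <= last_residue")
        # denominator of the torsion stationarity condition, d*theta^2 + c,
        # must not vanish for theta in [0, pi)
        lo = min(self.c, self.c + self.d * np.pi**2)
        hi = max(self.c, self.c + self.d * np.pi**2)
        if lo <= 0.0 <= hi:
            raise ValueError(
                f"segment [{self.first_residue},{self.last_residue}]: "
                "d*theta^2 + c changes sign or vanishes on [0, pi)"
            )

    def contains(self, residue: int) -> bool:
        return self.first_residue <= residue <= self.last_residue


@dataclass(frozen=True)
class EnergyModel:
    """Ordered soliton segments + excluded-volume constants.

    Segments must be non-overlapping, ordered, and jointly cover every
    residue that carries an angle (sites ``2..n-1`` hold theta and/or phi;
    covering ``1..n`` is also accepted).
    """

    segments: tuple
    hard_core_radius: float = HARD_CORE_RADIUS
    min_sequence_separation_for_core: int = MIN_CORE_SEPARATION

    def __init__(self, segments: Iterable[SolitonSegment],
                 hard_core_radius: float = HARD_CORE_RADIUS,
                 min_sequence_separation_for_core: int = MIN_CORE_SEPARATION):
        segs = tuple(segments)
        if not segs:
            raise ValueError("at least one segment required")
        for s0, s1 in zip(segs, segs[1:]):
            if s1.first_residue != s0.last_residue + 1:
                raise ValueError(
                    "segments must be ordered, contiguous and non-overlapping; "
                    f"gap or overlap between {s0.last_residue} and {s1.first_residue}"
                )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "hard_core_radius", float(hard_core_radius))
        object.__setattr__(self, "min_sequence_separation_for_core",
                           int(min_sequence_separation_for_core))

    @property
    def first_residue(self) -> int:
        return self.segments[0].first_residue

    @property
    def last_residue(self) -> int:
        return self.segments[-1].last_residue

    def covers(self, angles: AngularConformation) -> bool:
        # theta sites are 1..n-2, phi sites 2..n-2 (1-based); require coverage
        # of every theta-carrying site
        return self.first_residue <= 1 and self.last_residue >= angles.n_theta

    def site_parameters(self, angles: AngularConformation):
        """Per-theta-site parameter arrays (lam, m, a, b, c, d).

        Arrays are aligned with ``angles.theta`` (theta site ``i`` at index
        ``i-1``); the phi site ``i`` shares index ``i-1`` columns ``1:``.
        """
        if not self.covers(angles):
            raise ValueError(
                f"model covers residues {self.first_residue}..{self.last_residue} "
                f"but the chain has theta sites 1..{angles.n_theta}"
            )
        n = angles.n_theta
        out = np.empty((6, n))
        for seg in self.segments:
            lo = max(seg.first_residue, 1) - 1
            hi = min(seg.last_residue, n)
            if lo >= hi:
                continue
            out[:, lo:hi] = np.array(
                [seg.lambda_, seg.m, seg.a, seg.b, seg.c, seg.d]
            )[:, None]
        return out


def _angular_terms(angles: AngularConformation, params: np.ndarray) -> float:
    th, ph = angles.theta, angles.phi
    lam, m, a, b, c, d = params
    pair = np.sum((th[1:] - th[:-1]) ** 2)
    quart = np.sum(lam * (th**2 - m**2) ** 2)
    # phi site i (1-based 2..n-2) shares parameter index i-1 with theta site i
    th_p = th[1:]
    lamp, mp, ap, bp, cp, dp = params[:, 1:]
    tors = np.sum(0.5 * dp * th_p**2 * ph**2 + 0.5 * cp * ph**2
                  - bp * th_p**2 * ph - ap * ph)
    return float(pair + quart + tors)


def angular_free_energy(angles: AngularConformation, model: EnergyModel) -> float:
    """The angle-dependent part of the free energy (no excluded volume)."""
    return _angular_terms(angles, model.site_parameters(angles))


def free_energy(angles: AngularConformation, model: EnergyModel,
                chain: CAlphaChain | None = None):
    """Full free energy evaluation.

    Returns ``(F, hard_core_violated)``.  The angular terms depend on the
    internal coordinates only (hence are invariant under rigid motions of the
    chain); the hard-core flag is computed on the reconstructed coordinates
    (or on ``chain`` if the caller already has them).
    """
    F = angular_free_energy(angles, model)
    if chain is None:
        chain = angles_to_coords(angles)
    flag = has_hard_core_violation(
        chain, model.hard_core_radius, model.min_sequence_separation_for_core
    )
    return F, flag


def delta_free_energy(angles: AngularConformation, model: EnergyModel,
                      site: int, which: str, new_value: float) -> float:
    """Angular free-energy change of a single-angle update.

    ``site`` is the 1-based angle site (theta: ``1..n-2``, phi: ``2..n-2``).
    Only the terms containing the changed angle are re-evaluated; the result
    equals the difference of two full evaluations to machine precision.  The
    excluded-volume constraint is *not* checked here (the Monte Carlo engine
    rejects hard-core violating proposals separately).
    """
    th, ph = angles.theta, angles.phi
    params = model.site_parameters(angles)
    j = site - 1  # array index of theta_site; phi_site sits at ph[site - 2]
    if which == "theta":
        if not 1 <= site <= angles.n_theta:
            raise ValueError(f"no theta at site {site}")
        lam, m, a, b, c, d = params[:, j]
        old = th[j]

        def local(x):
            e = lam * (x**2 - m**2) ** 2
            if j > 0:
                e += (x - th[j - 1]) ** 2
            if j < th.size - 1:
                e += (th[j + 1] - x) ** 2
            if site >= 2:  # theta site also carries phi
                p = ph[site - 2]
                e += 0.5 * d * x**2 * p**2 - b * x**2 * p
            return e

        return float(local(new_value) - local(old))
    elif which == "phi":
        if not 2 <= site <= angles.n_theta:
            raise ValueError(f"no phi at site {site}")
        lam, m, a, b, c, d = params[:, j]
        t2 = th[j] ** 2
        old = ph[site - 2]

        def localp(p):
            return 0.5 * d * t2 * p**2 + 0.5 * c * p**2 - b * t2 * p - a * p

        return float(localp(new_value) - localp(old))
    raise ValueError("which must be 'theta' or 'phi'")


def hard_core_violations(chain: CAlphaChain, radius: float = HARD_CORE_RADIUS,
                         min_separation: int = MIN_CORE_SEPARATION):
    """All residue pairs (1-based, i < j) with |i-j| >= min_separation closer
    than ``radius`` (strict inequality: contact exactly at the radius is
    allowed)."""
    tree = cKDTree(chain.positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    out = []
    pos = chain.positions
    for i, j in pairs:
        if j - i >= min_separation and np.linalg.norm(pos[i] - pos[j]) < radius:
            out.append((int(i) + 1, int(j) + 1))
    out.sort()
    return out


def has_hard_core_violation(chain: CAlphaChain, radius: float = HARD_CORE_RADIUS,
                            min_separation: int = MIN_CORE_SEPARATION) -> bool:
    tree = cKDTree(chain.positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return False
    sep_ok = pairs[:, 1] - pairs[:, 0] >= min_separation
    if not np.any(sep_ok):
        return False
    pos = chain.positions
    d = np.linalg.norm(pos[pairs[sep_ok, 0]] - pos[pairs[sep_ok, 1]], axis=1)
    return bool(np.any(d < radius))


# ---------------------------------------------------------------------------
# parameter-file round trip
#
# Plain-text schema, one record per segment:
#
#   # knotfold energy model v1
#   hard_core_radius 3.8
#   min_sequence_separation_for_core 2
#   # first last lambda m a b c d
#   segment 1 15 2.0 1.5707963267948966 0.0 0.0 1.0 0.0
#   ...

def write_parameter_file(model: EnergyModel, path) -> None:
    lines = ["# knotfold energy model v1",
             f"hard_core_radius {model.hard_core_radius!r}",
             f"min_sequence_separation_for_core {model.min_sequence_separation_for_core}",
             "# segment <first> <last> <lambda> <m> <a> <b> <c> <d>"]
    for s in model.segments:
        lines.append(
            "segment "
            f"{s.first_residue} {s.last_residue} "
            f"{s.lambda_!r} {s.m!r} {s.a!r} {s.b!r} {s.c!r} {s.d!r}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameter_file(path) -> EnergyModel:
    radius = HARD_CORE_RADIUS
    min_sep = MIN_CORE_SEPARATION
    segs = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "hard_core_radius":
                radius = float(tok[1])
            elif tok[0] == "min_sequence_separation_for_core":
                min_sep = int(tok[1])
            elif tok[0] == "segment":
                first, last = int(tok[1]), int(tok[2])
                lam, m, a, b, c, d = map(float, tok[3:9])
                segs.append(SolitonSegment(first, last, lam, m, a, b, c, d))
            else:
                raise ValueError(f"unrecognized record: {line!r}")
    return EnergyModel(segs, radius, min_sep)
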