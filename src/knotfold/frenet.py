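"""Discrete Frenet geometry of a virtual C-alpha backbone.

A protein backbone reduced to its C-alpha trace is a piecewise-linear space
curve.  Attaching an orthonormal (normal, binormal, tangent) triad to each
virtual bond turns the curve into a sequence of frame rotations, and the two
rotation angles per step -- the virtual bond angle ``theta`` and the virtual
torsion angle ``phi`` -- are a complete set of internal coordinates: together
with the (essentially constant, 3.8 Angstrom) bond length they determine the
chain up to a global rigid motion.

Conventions
-----------
With 1-based residue indices ``i = 1..n``:

* tangents ``t_i = (r_{i+1} - r_i)/|r_{i+1} - r_i|`` exist for ``i = 1..n-1``;
* binormals ``b_i = t_{i-1} x t_i / |t_{i-1} x t_i|`` and normals
  ``n_i = b_i x t_i`` exist for ``i = 2..n-1``;
* bond angles ``theta_i = arccos(t_{i+1} . t_i)`` exist for ``i = 1..n-2``;
* torsion angles ``phi_i = sign[(b_i x b_{i+1}) . t_i] arccos(b_i . b_{i+1})``
  exist for ``i = 2..n-2``.

Frames are transported by ``(n,b,t)_{i+1} = exp(theta_i T^2) exp(phi_i T^3)
(n,b,t)_i`` where ``(T^a)_{jk} = eps_{ajk}``; the first transport step carries
no torsion (the overall twist of the first bond is part of the rigid-motion
gauge fixed by the seed frame).  The sign convention makes a right-handed
alpha-helix come out with ``phi = +1``.

theta is stored clipped to ``[0, pi)`` and phi wrapped to ``[-pi, pi)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BOND_LENGTH = 3.8
"""Mean C-alpha virtual bond length in Angstrom (PDB average)."""

__all__ = [
    "BOND_LENGTH",
    "CAlphaChain",
    "FrenetFrames",
    "AngularConformation",
    "DegenerateGeometryError",
    "DegenerateGeometryWarning",
    "compute_frames",
    "coords_to_angles",
    "angles_to_coords",
    "wrap_angle",
]

_COLLINEAR_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Two consecutive tangents are parallel, so a binormal is undefined.

    Carries the 1-based site index of the first undefined binormal.
    """

    def __init__(self, site: int):
        self.site = site
        super().__init__(
            f"binormal undefined at residue {site}: consecutive tangents are collinear"
        )


class DegenerateGeometryWarning(UserWarning):
    """A degenerate binormal was patched by the inheritance convention."""


def wrap_angle(x):
    """Wrap angle(s) to ``[-pi, pi)``."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class CAlphaChain:
    """Ordered C-alpha positions of one chain, in Angstrom.

    ``positions`` is an ``(n, 3)`` float array, ``n >= 4``.
    """

    positions: np.ndarray

    def __post_init__(self):
        pos = np.ascontiguousarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if pos.shape[0] < 4:
            raise ValueError("a chain needs at least 4 residues")
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if np.any(d == 0.0):
            raise ValueError("consecutive positions coincide")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CAlphaChain":
        """Rigidly move the chain: ``r -> r @ rotation.T + translation``."""
        return CAlphaChain(self.positions @ np.asarray(rotation).T + translation)


@dataclass(frozen=True)
class FrenetFrames:
    """Discrete Frenet triads along a chain.

    ``tangents`` has shape ``(n-1, 3)`` (bonds ``i = 1..n-1``); ``binormals``
    and ``normals`` have shape ``(n-2, 3)`` and belong to sites ``i = 2..n-1``.
    ``degenerate`` lists the 1-based sites whose binormal was inherited from
    the previous defined site (collinear tangents).
    """

    tangents: np.ndarray
    binormals: np.ndarray
    normals: np.ndarray
    degenerate: tuple = field(default_factory=tuple)


@dataclass
class AngularConformation:
    """Internal coordinates of a chain: bond angles and torsion angles.

    ``theta`` holds ``n - 2`` bond angles in ``[0, pi)`` for sites
    ``i = 1..n-2`` and ``phi`` holds ``n - 3`` torsion angles in ``[-pi, pi)``
    for sites ``i = 2..n-2`` (1-based).  This is the state space of the
    Monte Carlo engine.
    """

    theta: np.ndarray
    phi: np.ndarray
    bond_length: float = BOND_LENGTH

    def __post_init__(self):
        self.theta = np.ascontiguousarray(self.theta, dtype=float)
        self.phi = np.ascontiguousarray(self.phi, dtype=float)
        if self.theta.ndim != 1 or self.phi.ndim != 1:
            raise ValueError("theta and phi must be 1-D")
        if self.phi.size != self.theta.size - 1:
            raise ValueError(
                "inconsistent lengths: expected len(phi) == len(theta) - 1 "
                f"(one chain), got {self.phi.size} and {self.theta.size}"
            )
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if np.any(self.theta < 0.0) or np.any(self.theta >= np.pi):
            raise ValueError("theta out of range [0, pi)")
        if np.any(self.phi < -np.pi) or np.any(self.phi >= np.pi):
            raise ValueError("phi out of range [-pi, pi)")

    @property
    def n_residues(self) -> int:
        return self.theta.size + 2

    @property
    def n_theta(self) -> int:
        return self.theta.size

    @property
    def n_phi(self) -> int:
        return self.phi.size

    def copy(self) -> "AngularConformation":
        return AngularConformation(self.theta.copy(), self.phi.copy(), self.bond_length)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def compute_frames(chain: CAlphaChain, on_degenerate: str = "raise") -> FrenetFrames:
    """Compute the discrete Frenet triads of a chain.

    Parameters
    ----------
    chain:
        The C-alpha trace.
    on_degenerate:
        ``"raise"`` (default) raises :class:`DegenerateGeometryError` at the
        first site with collinear consecutive tangents; ``"inherit"`` applies
        the tie-break convention instead: the binormal is copied from the
        previous defined site (or, if there is none, from the first defined
        site downstream; a fully straight chain gets an arbitrary normal).

    Returns
    -------
    FrenetFrames
        Orthonormal right-handed triads, ``(n x b) . t = +1``.
    """
    if on_degenerate not in ("raise", "inherit"):
        raise ValueError("on_degenerate must be 'raise' or 'inherit'")
    t = _unit(np.diff(chain.positions, axis=0))
    cross = np.cross(t[:-1], t[1:])
    norms = np.linalg.norm(cross, axis=1)
    bad = norms < _COLLINEAR_TOL
    degenerate = []
    if np.any(bad):
        first_bad = int(np.argmin(~bad))
        if on_degenerate == "raise":
            # 1-based site of the binormal b_{i}: cross index k -> site k + 2
            raise DegenerateGeometryError(first_bad + 2)
        degenerate = [int(k) + 2 for k in np.nonzero(bad)[0]]
    b = np.empty_like(cross)
    good = ~bad
    b[good] = cross[good] / norms[good][:, None]
    if np.any(bad):
        if not np.any(good):
            # straight chain: any unit vector orthogonal to t works
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(ref, t[0])) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            b[:] = _unit(np.cross(t[0], ref))
        else:
            # inherit from previous defined site; leading run inherits backward
            idx_good = np.nonzero(good)[0]
            for k in np.nonzero(bad)[0]:
                prev = idx_good[idx_good < k]
                src = prev[-1] if prev.size else idx_good[0]
                b[k] = b[src]
    n = np.cross(b, t[1:])
    return FrenetFrames(t, b, n, tuple(degenerate))


def coords_to_angles(chain: CAlphaChain, on_degenerate: str = "inherit") -> AngularConformation:
    """Extract virtual bond and torsion angles from C-alpha coordinates.

    ``theta_i = arccos(t_{i+1} . t_i)`` and
    ``phi_i = sign[(b_i x b_{i+1}) . t_i] arccos(b_i . b_{i+1})``.

    Degenerate (collinear-tangent) sites are handled by the binormal
    inheritance convention by default, which assigns ``phi = 0`` across a
    straight stretch; a :class:`DegenerateGeometryWarning` records the sites.
    The mean observed bond length is stored on the result.
    """
    frames = compute_frames(chain, on_degenerate=on_degenerate)
    if frames.degenerate:
        warnings.warn(
            f"degenerate binormals at residues {frames.degenerate}; "
            "inherited-binormal convention applied (phi := 0 across straight runs)",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    t, b = frames.tangents, frames.binormals
    theta = np.arccos(np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1.0, 1.0))
    theta = np.clip(theta, 0.0, np.nextafter(np.pi, 0.0))
    cosphi = np.clip(np.einsum("ij,ij->i", b[:-1], b[1:]), -1.0, 1.0)
    # t aligned with b_i: binormal index k (site k+2) pairs with tangent t_{k+2}
    sign = np.sign(np.einsum("ij,ij->i", np.cross(b[:-1], b[1:]), t[1:-1]))
    sign[sign == 0.0] = 1.0
    phi = wrap_angle(sign * np.arccos(cosphi))
    return AngularConformation(theta, phi, float(chain.bond_lengths().mean()))


def _step_rotation(theta: float, phi: float) -> np.ndarray:
    """Transport matrix exp(theta T^2) exp(phi T^3) acting on frame rows (n, b, t)."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    return np.array(
        [
            [ct * cp, ct * sp, st],
            [-sp, cp, 0.0],
            [-st * cp, -st * sp, ct],
        ]
    )


DEFAULT_SEED_FRAME = (
    np.zeros(3),
    np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
)
"""Default (origin, frame) gauge: first residue at the origin, first bond along +z."""


def angles_to_coords(angles: AngularConformation, seed_frame=None) -> CAlphaChain:
    """Rebuild C-alpha coordinates from internal coordinates.

    The chain is unique up to a global rigid motion; ``seed_frame`` is a pair
    ``(origin, F)`` with ``F`` a 3x3 matrix whose rows are the initial
    ``(n, b, t)`` triad.  All reconstructed bond lengths equal
    ``angles.bond_length`` to machine precision.
    """
    origin, frame = DEFAULT_SEED_FRAME if seed_frame is None else seed_frame
    frame = np.asarray(frame, dtype=float)
    theta, phi = angles.theta, angles.phi
    n = angles.n_residues
    tangents = np.empty((n - 1, 3))
    tangents[0] = frame[2]
    F = frame
    for k in range(n - 2):
        # torsion is absent on the first step (phi_1 does not exist)
        F = _step_rotation(theta[k], phi[k - 1] if k > 0 else 0.0) @ F
        tangents[k + 1] = F[2]
    pos = np.empty((n, 3))
    pos[0] = origin
    np.cumsum(angles.bond_length * tangents, axis=0, out=pos[1:])
    pos[1:] += origin
    return CAlphaChain(pos)
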