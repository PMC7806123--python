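"""Knot and slipknot detection on open polygonal chains.

An open C-alpha chain has no knot type in the strict mathematical sense; the
standard operational definition closes the chain "at infinity" and classifies
the resulting polygon.  The pipeline here is

1. ray closure: both termini are extended radially outward (away from the
   chain centroid) to a far sphere and joined there; several randomly
   perturbed closures are generated and the knot types vote;
2. KMT reduction: vertices whose spanning triangle is crossed by no other
   segment are deleted iteratively -- this preserves the knot type and
   shrinks the polygon to a handful of vertices;
3. typing by the knot determinant |Delta(-1)|, computed from the crossing
   structure of a generic planar projection (Alexander matrix at t = -1).
   Determinant 1 -> unknot, 3 -> trefoil 3_1, 5 -> figure-eight 4_1,
   anything else -> other(det).

A *slipknot* is an open chain that is unknotted as a whole but contains a
knotted subchain: a threaded loop that would be a knot if the chain ended
earlier.  :func:`slipknot_scan` detects this by typing closed subchains over
a coarse-then-refined grid.

The determinant does not separate knots that share |Delta(-1)| (e.g. 3_1
from 8_19); for the state space relevant here -- unknot, trefoil,
figure-eight, slipknot -- it is a complete invariant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .frenet import CAlphaChain

__all__ = [
    "KnotReport",
    "ProjectionError",
    "close_chain",
    "kmt_reduce",
    "knot_determinant",
    "knot_type",
    "vote_knot_type",
    "slipknot_scan",
    "label_from_determinant",
]

_EPS = 1e-9


class ProjectionError(RuntimeError):
    """No generic planar projection found after the retry budget."""


@dataclass(frozen=True)
class KnotReport:
    """Topological screening result for one open chain.

    Residue ranges are 1-based inclusive.  ``is_slipknot`` implies the whole
    chain is unknotted and ``knotted_subchain`` is set.
    """

    whole_chain_type: str
    whole_chain_determinant: int
    is_slipknot: bool
    knotted_subchain: Optional[Tuple[int, int]]
    knotting_loop: Optional[Tuple[int, int]]
    threaded_segment: Optional[Tuple[int, int]]
    closure_votes: dict

    def __str__(self):
        lines = [f"whole-chain type: {self.whole_chain_type} "
                 f"(determinant {self.whole_chain_determinant})",
                 f"slipknot: {'yes' if self.is_slipknot else 'no'}"]
        if self.knotted_subchain:
            lines.append(f"knotted subchain: residues "
                         f"{self.knotted_subchain[0]}-{self.knotted_subchain[1]}")
        if self.knotting_loop:
            lines.append(f"knotting loop: residues "
                         f"{self.knotting_loop[0]}-{self.knotting_loop[1]}")
        if self.threaded_segment:
            lines.append(f"threaded segment: residues "
                         f"{self.threaded_segment[0]}-{self.threaded_segment[1]}")
        lines.append("closure votes: " + ", ".join(
            f"{k}: {v}" for k, v in sorted(self.closure_votes.items())))
        return "\n".join(lines)


def label_from_determinant(det: int) -> str:
    return {1: "unknot", 3: "3_1", 5: "4_1"}.get(det, f"other({det})")


# ---------------------------------------------------------------------------
# closure

def close_chain(points: np.ndarray, n_rays: int = 20,
                rng: np.random.Generator | None = None,
                perturbation: float = 0.35):
    """Generate closed polygons from an open chain by radial ray closure.

    If the termini are already within one mean bond length they are joined
    directly (a single closure).  Otherwise each closure pushes both termini
    outward along the (randomly perturbed) centroid->terminus directions to a
    far sphere and joins them across it, so the closure arc cannot thread the
    chain.  Returns a list of ``(m, 3)`` vertex arrays, each understood as a
    closed polygon (last vertex connects back to the first).
    """
    pts = points.positions if isinstance(points, CAlphaChain) else np.asarray(points, float)
    rng = np.random.default_rng(0) if rng is None else rng
    bond = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())
    if np.linalg.norm(pts[0] - pts[-1]) <= bond:
        return [pts.copy()]
    c = pts.mean(axis=0)
    R = 10.0 * float(np.linalg.norm(pts - c, axis=1).max()) + 10.0 * bond
    closures = []
    for _ in range(n_rays):
        polys = []
        for end in (pts[0], pts[-1]):
            u = end - c
            nu = np.linalg.norm(u)
            u = u / nu if nu > _EPS else rng.normal(size=3)
            u = u + perturbation * rng.normal(size=3)
            polys.append(end + R * u / np.linalg.norm(u))
        f_start, f_end = polys
        # join across the sphere through an outer waypoint so the straight
        # joining path cannot pass near the chain
        w = (f_start - c) + (f_end - c)
        nw = np.linalg.norm(w)
        if nw < 1e-3 * R:  # near-antipodal rays
            w = np.cross(f_start - c, rng.normal(size=3))
            nw = np.linalg.norm(w)
        mid = c + 2.0 * R * w / nw
        closures.append(np.vstack([pts, f_end, mid, f_start]))
    return closures


# ---------------------------------------------------------------------------
# KMT reduction

def _triangle_blocked(poly: np.ndarray, i: int) -> bool:
    """Is the triangle spanned by vertices (i-1, i, i+1) of the closed polygon
    crossed by any non-incident segment?"""
    m = len(poly)
    A, B, C = poly[(i - 1) % m], poly[i], poly[(i + 1) % m]
    u, v = B - A, C - A
    nrm = np.cross(u, v)
    area2 = np.linalg.norm(nrm)
    if area2 < _EPS:  # degenerate (collinear) triangle: removal is free
        return False
    # candidate segments: all except the four incident to vertices A, B, C
    excl = {(i - 2) % m, (i - 1) % m, i, (i + 1) % m}
    idx = np.array([k for k in range(m) if k not in excl])
    if idx.size == 0:
        return False
    P = poly[idx]
    Q = poly[(idx + 1) % m]
    D = Q - P
    denom = D @ nrm
    w = A - P
    # segment-plane intersection parameter t; parallel segments are treated
    # as blocking only if they lie (numerically) in the triangle's plane
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w @ nrm) / denom
    parallel = np.abs(denom) < _EPS * area2
    close_to_plane = np.abs(w @ nrm) < _EPS * area2
    coplanar = parallel & close_to_plane
    if np.any(coplanar):
        # in-plane segments: 2D overlap test against the closed triangle
        if _coplanar_blocks(P[coplanar], Q[coplanar], A, u, v):
            return True
    cand = ~parallel & (t >= -_EPS) & (t <= 1.0 + _EPS)
    if not np.any(cand):
        return False
    X = P[cand] + t[cand, None] * D[cand]
    return _points_in_triangle(X, A, u, v)


def _points_in_triangle(X, A, u, v, tol=1e-7) -> bool:
    """Any of the points X inside triangle (A, A+u, A+v), barycentrically."""
    uu, vv, uv = u @ u, v @ v, u @ v
    det = uu * vv - uv * uv
    wx = np.atleast_2d(X) - A
    wu = wx @ u
    wv = wx @ v
    s = (vv * wu - uv * wv) / det
    r = (uu * wv - uv * wu) / det
    return bool(np.any((s >= -tol) & (r >= -tol) & (s + r <= 1.0 + tol)))


def _coplanar_blocks(P, Q, A, u, v) -> bool:
    """Do any in-plane segments P->Q intersect the triangle (A, A+u, A+v)?

    Works in the triangle's 2D coordinates; a segment blocks if an endpoint
    lies inside the triangle or if it crosses one of the edges.
    """
    if _points_in_triangle(P, A, u, v) or _points_in_triangle(Q, A, u, v):
        return True
    # edge-crossing test in the (u, v) basis
    G = np.linalg.pinv(np.c_[u, v])  # 3D -> barycentric-ish 2D coords
    p2 = (P - A) @ G.T
    q2 = (Q - A) @ G.T
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    for e0, e1 in ((0, 1), (1, 2), (2, 0)):
        a, b = tri[e0], tri[e1]
        d1 = b - a
        for k in range(len(p2)):
            d2 = q2[k] - p2[k]
            den = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(den) < 1e-12:
                continue
            diff = p2[k] - a
            s = (diff[0] * d2[1] - diff[1] * d2[0]) / den
            t = (diff[0] * d1[1] - diff[1] * d1[0]) / den
            if -1e-9 < s < 1 + 1e-9 and -1e-9 < t < 1 + 1e-9:
                return True
    return False


def kmt_reduce(polygon: np.ndarray, min_vertices: int = 3) -> np.ndarray:
    """Simplify a closed polygon without changing its knot type.

    Iteratively deletes any vertex whose spanning triangle is intersected by
    no other segment of the polygon; terminates when a full pass makes no
    deletion (a triangle is returned unchanged).
    """
    poly = np.asarray(polygon, dtype=float).copy()
    changed = True
    while changed and len(poly) > min_vertices:
        changed = False
        i = 0
        while i < len(poly) and len(poly) > min_vertices:
            if not _triangle_blocked(poly, i):
                poly = np.delete(poly, i, axis=0)
                changed = True
            else:
                i += 1
    return poly


# ---------------------------------------------------------------------------
# determinant from a planar diagram

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def _diagram_crossings(poly: np.ndarray):
    """All transversal crossings of the projection onto the xy-plane.

    Returns a list of ``(u_under, u_over)`` curve parameters (vertex index +
    fraction along the segment).  Raises :class:`ProjectionError` on any
    degeneracy (near-parallel overlap, crossing too close to a vertex, or a
    z-tie).
    """
    m = len(poly)
    xy = poly[:, :2]
    z = poly[:, 2]
    P = xy
    Q = xy[(np.arange(m) + 1) % m]
    D = Q - P
    crossings = []
    guard = 1e-7
    for i in range(m):
        for j in range(i + 2, m):
            if i == 0 and j == m - 1:
                continue  # adjacent around the cycle
            denom = D[i, 0] * D[j, 1] - D[i, 1] * D[j, 0]
            diff = P[j] - P[i]
            if abs(denom) < guard * (np.linalg.norm(D[i]) * np.linalg.norm(D[j]) + _EPS):
                # parallel in projection: degenerate only if they overlap
                if abs(diff[0] * D[i, 1] - diff[1] * D[i, 0]) < guard:
                    raise ProjectionError("overlapping parallel segments in projection")
                continue
            s = (diff[0] * D[j, 1] - diff[1] * D[j, 0]) / denom
            t = (diff[0] * D[i, 1] - diff[1] * D[i, 0]) / denom
            if -guard < s < guard or 1 - guard < s < 1 + guard \
               or -guard < t < guard or 1 - guard < t < 1 + guard:
                if (-guard < s < 1 + guard) and (-guard < t < 1 + guard):
                    raise ProjectionError("crossing at a vertex")
                continue
            if 0 < s < 1 and 0 < t < 1:
                zi = z[i] + s * (z[(i + 1) % m] - z[i])
                zj = z[j] + t * (z[(j + 1) % m] - z[j])
                if abs(zi - zj) < guard:
                    raise ProjectionError("z-tie at a crossing")
                ui, uj = i + s, j + t
                if zi < zj:
                    crossings.append((ui, uj))
                else:
                    crossings.append((uj, ui))
    return crossings


def _determinant_from_crossings(crossings) -> int:
    """Knot determinant |Delta(-1)| from the crossing list.

    Arcs run between consecutive underpasses along the curve; each crossing
    contributes the t=-1 Alexander relation row  -x_in - x_out + 2 x_over
    (independent of the crossing sign).
    """
    mC = len(crossings)
    if mC == 0:
        return 1
    unders = sorted(c[0] for c in crossings)

    def arc_of(u: float) -> int:
        # arc k spans (unders[k-1], unders[k]]; values above the last wrap to arc 0
        k = int(np.searchsorted(unders, u, side="left"))
        return k % mC

    M = np.zeros((mC, mC))
    for row, (u_under, u_over) in enumerate(crossings):
        k_in = arc_of(u_under)          # arc ending at this underpass
        k_out = (k_in + 1) % mC         # arc starting here
        k_over = arc_of(u_over)
        M[row, k_in] += -1.0
        M[row, k_out] += -1.0
        M[row, k_over] += 2.0
    if mC == 1:
        return 1
    sub = M[:-1, :-1]
    det = np.linalg.det(sub)
    return int(abs(round(det)))


def knot_determinant(polygon: np.ndarray, rng: np.random.Generator | None = None,
                     max_retries: int = 8, reduce_first: bool = True) -> int:
    """|Delta(-1)| of a closed polygon; retries random seeded rotations until
    the projection is generic."""
    rng = np.random.default_rng(0) if rng is None else rng
    poly = kmt_reduce(polygon) if reduce_first else np.asarray(polygon, float)
    if len(poly) <= 3:
        return 1
    for attempt in range(max_retries):
        R = _random_rotation(rng) if attempt else np.eye(3)
        try:
            return _determinant_from_crossings(_diagram_crossings(poly @ R.T))
        except ProjectionError:
            continue
    raise ProjectionError(
        f"no generic projection after {max_retries} random rotations")


def knot_type(polygon: np.ndarray, rng: np.random.Generator | None = None):
    """Type one closed polygon.  Returns ``(label, determinant)``."""
    det = knot_determinant(polygon, rng)
    return label_from_determinant(det), det


def vote_knot_type(chain, n_rays: int = 20,
                   rng: np.random.Generator | None = None):
    """Close an open chain ``n_rays`` ways and take the majority knot type.

    Returns ``(label, determinant, votes)`` where ``votes`` is a label ->
    count tally over closures.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    votes: Counter = Counter()
    dets = {}
    for poly in close_chain(chain, n_rays=n_rays, rng=rng):
        try:
            label, det = knot_type(poly, rng)
        except ProjectionError:
            continue
        votes[label] += 1
        dets.setdefault(label, det)
    if not votes:
        raise ProjectionError("every closure failed to project generically")
    label = votes.most_common(1)[0][0]
    return label, dets[label], dict(votes)


# ---------------------------------------------------------------------------
# slipknot scanning

def _subchain_knotted(pts: np.ndarray, rng, n_rays: int) -> bool:
    label, _, votes = vote_knot_type(pts, n_rays=n_rays, rng=rng)
    return label != "unknot"


def slipknot_scan(chain, seed: int = 0, stride: int = 5, min_len: int = 10,
                  n_rays_whole: int = 20, n_rays_sub: int = 5) -> KnotReport:
    """Screen an open chain for knots and slipknots.

    The whole chain is typed by majority-vote ray closure.  Closed subchains
    ``(i..j)`` are then scanned over a stride-``stride`` grid, with local
    refinement (stride 1 within +-(stride-1)) around the extremal hits, to
    find the maximal and minimal knotted subchains.  The minimal knotted
    subchain is reported as the knotting loop; the part of the chain beyond
    the maximal knotted subchain (the longer free end) is the threaded
    segment.
    """
    pts = chain.positions if isinstance(chain, CAlphaChain) else np.asarray(chain, float)
    n = len(pts)
    if n < min_len:
        raise ValueError(f"chain too short to screen (n={n} < {min_len})")
    rng = np.random.default_rng(seed)
    whole_label, whole_det, votes = vote_knot_type(pts, n_rays=n_rays_whole, rng=rng)

    def knotted(i, j):  # 1-based inclusive
        return _subchain_knotted(pts[i - 1:j], rng, n_rays_sub)

    hits = []
    starts = list(range(1, n - min_len + 2, stride))
    for i in starts:
        for j in range(i + min_len - 1, n + 1, stride):
            if (i, j) == (1, n):
                continue
            if knotted(i, j):
                hits.append((i, j))
    knotted_sub = knot_loop = threaded = None
    if hits:
        # maximal knotted subchain: widen the widest coarse hit
        i0, j0 = max(hits, key=lambda ij: ij[1] - ij[0])
        i_max, j_max = i0, j0
        for i in range(max(1, i0 - stride + 1), i0 + 1):
            if i < i0 and knotted(i, j0):
                i_max = i
                break
        for j in range(min(n, j0 + stride - 1), j0 - 1, -1):
            if j > j0 and knotted(i_max, j):
                j_max = j
                break
        # minimal knotted subchain: shrink the tightest coarse hit
        i1, j1 = min(hits, key=lambda ij: ij[1] - ij[0])
        i_min, j_min = i1, j1
        for i in range(i1 + stride - 1, i1 - 1, -1):
            if i > i1 and j1 - i + 1 >= min_len and knotted(i, j1):
                i_min = i
                break
        for j in range(j1 - stride + 1, j1 + 1):
            if j < j1 and j - i_min + 1 >= min_len and knotted(i_min, j):
                j_min = j
                break
        knotted_sub = (i_max, j_max)
        knot_loop = (i_min, j_min)
        head, tail = i_max - 1, n - j_max
        if max(head, tail) > 0:
            threaded = (j_max + 1, n) if tail >= head else (1, i_max - 1)
    is_slip = whole_label == "unknot" and knotted_sub is not None
    return KnotReport(
        whole_chain_type=whole_label,
        whole_chain_determinant=whole_det,
        is_slipknot=is_slip,
        knotted_subchain=knotted_sub,
        knotting_loop=knot_loop,
        threaded_segment=threaded,
        closure_votes=votes,
    )
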