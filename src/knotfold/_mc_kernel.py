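"""Numba-compiled inner loop of the Monte Carlo engine.

The kernel mutates the angular state in place and mirrors, step for step,
the pure-Python reference loop in :mod:`knotfold.mc` (the two are asserted
bit-identical in the test suite).  All randomness enters through
pre-generated streams, so a seeded `numpy` Generator fully determines the
trajectory regardless of which loop executes it.

Per step (stream layout: u_move, u_site, z, u_a, u_b):

* with probability ``theta_prob`` a heat-bath bond-angle update, otherwise a
  Glauber torsion update at a uniformly random site;
* torsion proposal ``phi' = phi + (pi/2) z`` (z standard normal), accepted
  with the Glauber probability ``exp(-beta dF)/(1 + exp(-beta dF))`` using
  ``u_a``; proposals that violate the hard core are rejected outright;
* bond angle redrawn from ``P(theta) ~ exp(-beta_hb F_theta)`` discretized
  on a midpoint grid over ``[0, pi)`` (inverse-CDF with ``u_a``, uniform
  within the bin with ``u_b``); hard-core violating draws are rejected;
* ``beta *= multiplier`` after every step.

Coordinates are rebuilt from the angles after every accepted move (the
angular update is equivalent to a rigid rotation of the downstream
sub-chain; rebuilding from internal coordinates keeps the cache exactly
consistent), and the angular free energy is tracked incrementally.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chunk", "rebuild_positions", "hard_core_clash", "NREC_FIELDS"]

NREC_FIELDS = 3  # beta, angular energy, radius of gyration


@njit(cache=True)
def rebuild_positions(theta, phi, bond, pos):
    """Reconstruct positions from angles into ``pos`` (n, 3), gauge-fixed to
    origin/identity frame.  Mirrors frenet.angles_to_coords."""
    n = theta.shape[0] + 2
    # frame rows: n, b, t
    F = np.eye(3)
    pos[0, 0] = 0.0
    pos[0, 1] = 0.0
    pos[0, 2] = 0.0
    pos[1, 0] = bond * F[2, 0]
    pos[1, 1] = bond * F[2, 1]
    pos[1, 2] = bond * F[2, 2]
    G = np.empty((3, 3))
    for k in range(n - 2):
        th = theta[k]
        ph = phi[k - 1] if k > 0 else 0.0
        ct, st = np.cos(th), np.sin(th)
        cp, sp = np.cos(ph), np.sin(ph)
        # R = [[ct*cp, ct*sp, st], [-sp, cp, 0], [-st*cp, -st*sp, ct]] @ F
        for col in range(3):
            a = F[0, col]
            b_ = F[1, col]
            c = F[2, col]
            G[0, col] = ct * cp * a + ct * sp * b_ + st * c
            G[1, col] = -sp * a + cp * b_
            G[2, col] = -st * cp * a - st * sp * b_ + ct * c
        for rr in range(3):
            for cc in range(3):
                F[rr, cc] = G[rr, cc]
        pos[k + 2, 0] = pos[k + 1, 0] + bond * F[2, 0]
        pos[k + 2, 1] = pos[k + 1, 1] + bond * F[2, 1]
        pos[k + 2, 2] = pos[k + 1, 2] + bond * F[2, 2]


@njit(cache=True)
def hard_core_clash(pos, radius, min_sep):
    n = pos.shape[0]
    r2 = radius * radius
    for i in range(n):
        for j in range(i + min_sep, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < r2:
                return True
    return False


@njit(cache=True)
def _delta_phi_energy(theta, phi, params, s, new_phi):
    """Local angular-energy change for phi at 1-based site s."""
    j = s - 1
    a = params[2, j]
    b = params[3, j]
    c = params[4, j]
    d = params[5, j]
    t2 = theta[j] * theta[j]
    p0 = phi[s - 2]
    e0 = 0.5 * d * t2 * p0 * p0 + 0.5 * c * p0 * p0 - b * t2 * p0 - a * p0
    e1 = (0.5 * d * t2 * new_phi * new_phi + 0.5 * c * new_phi * new_phi
          - b * t2 * new_phi - a * new_phi)
    return e1 - e0


@njit(cache=True)
def _theta_local_energy(theta, phi, params, s, x):
    """All theta_s-dependent angular terms evaluated at theta_s = x."""
    j = s - 1
    lam = params[0, j]
    m = params[1, j]
    b = params[3, j]
    d = params[5, j]
    q = x * x - m * m
    e = lam * q * q
    if j > 0:
        e += (x - theta[j - 1]) * (x - theta[j - 1])
    if j < theta.shape[0] - 1:
        e += (theta[j + 1] - x) * (theta[j + 1] - x)
    if s >= 2:
        p = phi[s - 2]
        e += 0.5 * d * x * x * p * p - b * x * x * p
    return e


@njit(cache=True)
def _wrap(x):
    y = (x + np.pi) % (2.0 * np.pi) - np.pi
    if y >= np.pi:  # guard the half-open upper end
        y = -np.pi
    return y


@njit(cache=True)
def run_chunk(theta, phi, pos, params, beta0, multiplier, hb_ratio,
              theta_prob, radius, min_sep, bond, n_bins, rand,
              energy0, step_offset, record_stride, rec, rec_pos, rec_phi,
              check_state):
    """Advance the chain by ``rand.shape[1]`` Monte Carlo steps.

    Mutates ``theta``, ``phi``, ``pos`` in place; fills the record arrays at
    global steps divisible by ``record_stride`` (``rec`` rows indexed by
    global step // stride).  Returns ``(beta, energy, n_phi_accept,
    n_theta_accept)``.  ``check_state`` is scratch space ``(n, 3)``.
    """
    n_steps = rand.shape[1]
    n_theta = theta.shape[0]
    n_phi = phi.shape[0]
    beta = beta0
    energy = energy0
    acc_phi = 0
    acc_th = 0
    h = np.pi / n_bins
    weights = np.empty(n_bins)
    for step in range(n_steps):
        gstep = step_offset + step
        if record_stride > 0 and gstep % record_stride == 0:
            ridx = gstep // record_stride
            if ridx < rec.shape[0]:
                rec[ridx, 0] = beta
                rec[ridx, 1] = energy
                # radius of gyration
                cx = cy = cz = 0.0
                npos = pos.shape[0]
                for i in range(npos):
                    cx += pos[i, 0]
                    cy += pos[i, 1]
                    cz += pos[i, 2]
                cx /= npos
                cy /= npos
                cz /= npos
                s2 = 0.0
                for i in range(npos):
                    dx = pos[i, 0] - cx
                    dy = pos[i, 1] - cy
                    dz = pos[i, 2] - cz
                    s2 += dx * dx + dy * dy + dz * dz
                rec[ridx, 2] = np.sqrt(s2 / npos)
                for i in range(npos):
                    for cc in range(3):
                        rec_pos[ridx, i, cc] = pos[i, cc]
                for i in range(n_phi):
                    rec_phi[ridx, i] = phi[i]
        u_move = rand[0, step]
        u_site = rand[1, step]
        z = rand[2, step]
        u_a = rand[3, step]
        u_b = rand[4, step]
        if u_move >= theta_prob:
            # Glauber torsion move
            s = 2 + int(u_site * n_phi)  # 1-based phi site
            if s > n_phi + 1:
                s = n_phi + 1
            old = phi[s - 2]
            new = _wrap(old + 0.5 * np.pi * z)
            dF = _delta_phi_energy(theta, phi, params, s, new)
            x = beta * dF
            if x > 700.0:
                p_acc = 0.0
            elif x < -700.0:
                p_acc = 1.0
            else:
                e = np.exp(-x)
                p_acc = e / (1.0 + e)
            # acceptance requires both the Glauber draw and steric clearance;
            # testing the (cheap) draw first skips the geometry rebuild for
            # most cold-phase proposals without changing the decision
            if u_a < p_acc:
                phi[s - 2] = new
                rebuild_positions(theta, phi, bond, check_state)
                phi[s - 2] = old
                if not hard_core_clash(check_state, radius, min_sep):
                    phi[s - 2] = new
                    energy += dF
                    for i in range(pos.shape[0]):
                        for cc in range(3):
                            pos[i, cc] = check_state[i, cc]
                    acc_phi += 1
        else:
            # heat-bath bond-angle move
            s = 1 + int(u_site * n_theta)
            if s > n_theta:
                s = n_theta
            beta_hb = hb_ratio * beta
            fmin = 1e300
            for mbin in range(n_bins):
                x = (mbin + 0.5) * h
                f = _theta_local_energy(theta, phi, params, s, x)
                weights[mbin] = f
                if f < fmin:
                    fmin = f
            total = 0.0
            for mbin in range(n_bins):
                arg = beta_hb * (weights[mbin] - fmin)
                # exp underflows to zero anyway beyond ~745; skipping it
                # keeps the enormous production beta_hb cheap
                w = 0.0 if arg > 746.0 else np.exp(-arg)
                weights[mbin] = w
                total += w
            target = u_a * total
            acc = 0.0
            chosen = n_bins - 1
            for mbin in range(n_bins):
                acc += weights[mbin]
                if acc >= target:
                    chosen = mbin
                    break
            new_theta = (chosen + u_b) * h
            if new_theta >= np.pi:
                new_theta = np.nextafter(np.pi, 0.0)
            old = theta[s - 1]
            dF = (_theta_local_energy(theta, phi, params, s, new_theta)
                  - _theta_local_energy(theta, phi, params, s, old))
            theta[s - 1] = new_theta
            rebuild_positions(theta, phi, bond, check_state)
            if hard_core_clash(check_state, radius, min_sep):
                theta[s - 1] = old
            else:
                energy += dF
                for i in range(pos.shape[0]):
                    for cc in range(3):
                        pos[i, cc] = check_state[i, cc]
                acc_th += 1
        beta *= multiplier
    return beta, energy, acc_phi, acc_th
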