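"""Ensemble observables: compactness, superposed RMSD, torsion fluctuations,
and final-state classification for folding/unfolding trajectories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frenet import AngularConformation, CAlphaChain, wrap_angle

__all__ = [
    "radius_of_gyration",
    "kabsch_rotation",
    "rmsd_superposed",
    "torsion_fluctuation_profile",
    "classify_final_state",
    "EnsembleSummary",
    "RMSD_SUCCESS_THRESHOLD",
]

RMSD_SUCCESS_THRESHOLD = 2.0
"""Default RMSD cut (Angstrom) below which a slipknotted final state counts as
a native refold.  Not a published value; see the methods note."""


def radius_of_gyration(chain) -> float:
    """Root-mean-square distance of the positions from their centroid, Angstrom."""
    pos = chain.positions if isinstance(chain, CAlphaChain) else np.asarray(chain, float)
    c = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - c) ** 2, axis=1))))


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation (det = +1, no reflection) minimizing |P @ R.T - Q|.

    P and Q must already be centered.
    """
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    return Vt.T @ D @ U.T


def rmsd_superposed(A, B) -> float:
    """Minimal RMSD between two equal-length chains over rotations and
    translations (reflections excluded), Angstrom."""
    P = A.positions if isinstance(A, CAlphaChain) else np.asarray(A, float)
    Q = B.positions if isinstance(B, CAlphaChain) else np.asarray(B, float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    R = kabsch_rotation(P, Q)
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))


def torsion_fluctuation_profile(phi_ensemble, native_phi):
    """Per-site circular torsion fluctuations of an ensemble.

    Parameters
    ----------
    phi_ensemble:
        ``(n_conformations, n_phi)`` array of torsion angles.
    native_phi:
        ``(n_phi,)`` native torsion angles (or an
        :class:`~knotfold.frenet.AngularConformation`).

    Returns
    -------
    (delta_phi, spread):
        ``delta_phi`` is the circular ensemble mean minus the native value,
        wrapped to ``[-pi, pi)``; ``spread`` is the circular standard
        deviation ``sqrt(-2 ln Rbar)`` per site (0 for a sharp ensemble).
    """
    if isinstance(native_phi, AngularConformation):
        native_phi = native_phi.phi
    ens = np.atleast_2d(np.asarray(phi_ensemble, dtype=float))
    native = np.asarray(native_phi, dtype=float)
    if ens.shape[1] != native.size:
        raise ValueError("ensemble and native torsion lengths differ")
    C = np.cos(ens).mean(axis=0)
    S = np.sin(ens).mean(axis=0)
    mean = np.arctan2(S, C)
    Rbar = np.clip(np.hypot(C, S), 1e-300, 1.0)
    spread = np.sqrt(-2.0 * np.log(Rbar))
    return wrap_angle(mean - native), spread


def classify_final_state(final: CAlphaChain, native: CAlphaChain,
                         rmsd_threshold: float = RMSD_SUCCESS_THRESHOLD,
                         knot_report=None) -> str:
    """Classify a final conformation of a heating/cooling cycle.

    Labels: ``native_slipknot`` (slipknotted and within ``rmsd_threshold`` of
    the native), ``misfold_trefoil`` (whole chain closes to a trefoil),
    ``misfold_unknotted`` (topologically trivial, no slipknot), ``other``.
    A precomputed :class:`~knotfold.topology.KnotReport` may be passed to
    avoid re-screening.
    """
    from .topology import slipknot_scan  # deferred: topology is heavier

    report = knot_report if knot_report is not None else slipknot_scan(final)
    if report.whole_chain_type == "3_1":
        return "misfold_trefoil"
    if report.is_slipknot and rmsd_superposed(final, native) < rmsd_threshold:
        return "native_slipknot"
    if report.whole_chain_type == "unknot" and not report.is_slipknot:
        return "misfold_unknotted"
    return "other"


@dataclass
class EnsembleSummary:
    """Aggregated per-record statistics of an ensemble of cycles.

    All arrays share the record grid of the schedule.  ``rg_sd``/``rmsd_sd``
    are NaN when the ensemble has a single cycle.  ``class_fractions`` maps
    final-state label -> fraction (summing to 1 over observed labels).
    """

    log10_beta: np.ndarray
    rg_mean: np.ndarray
    rg_sd: np.ndarray
    rmsd_mean: np.ndarray
    rmsd_sd: np.ndarray
    delta_phi: np.ndarray      # (n_records, n_phi) circular mean - native
    delta_phi_spread: np.ndarray
    class_fractions: dict
    n_cycles: int

    def to_frame(self):
        """Tabular view (one row per record) for plotting or text output."""
        import pandas as pd

        return pd.DataFrame({
            "log10_beta": self.log10_beta,
            "rg_mean": self.rg_mean,
            "rg_sd": self.rg_sd,
            "rmsd_mean": self.rmsd_mean,
            "rmsd_sd": self.rmsd_sd,
            "max_abs_delta_phi": np.abs(self.delta_phi).max(axis=1),
            "mean_delta_phi_spread": self.delta_phi_spread.mean(axis=1),
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
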