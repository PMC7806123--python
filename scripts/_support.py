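"""Shared factories and statistics helpers for the acceptance script."""

import numpy as np
from scipy import stats

from knotfold.energy import EnergyModel, SolitonSegment
from knotfold.frenet import AngularConformation
from knotfold.mc import MCState


def random_state(n, seed):
    rng = np.random.default_rng(seed)
    return AngularConformation(rng.uniform(0.2, 2.8, n - 2),
                               rng.uniform(-3, 3, n - 3))


def random_model(angles, seed, n_segments=2):
    rng = np.random.default_rng(seed + 1000)
    nt = angles.n_theta
    bounds = [1] + sorted(rng.choice(np.arange(2, nt), n_segments - 1,
                                     replace=False).tolist()) + [nt + 1]
    segs = [
        SolitonSegment(bounds[k], bounds[k + 1] - 1,
                       lambda_=rng.uniform(0.2, 3), m=rng.uniform(0.3, 2),
                       a=rng.normal(), b=rng.normal(),
                       c=rng.uniform(0.5, 2), d=rng.uniform(0, 0.5))
        for k in range(n_segments)
    ]
    return EnergyModel(segs)


def open_system(n=10, c=1.0, a=0.0, b=0.0, d=0.0, lam=1.0, m=0.3, beta=1.0,
                hb_ratio=1.0, seed=0, radius=3.8):
    """Near-straight chain: torsion/bond-angle moves are sterically free."""
    model = EnergyModel([SolitonSegment(1, n, lam, m, a, b, c, d)],
                        hard_core_radius=radius)
    angles = AngularConformation(np.full(n - 2, 0.3), np.zeros(n - 3))
    return MCState(angles, model, beta=beta, rng=np.random.default_rng(seed),
                   hb_ratio=hb_ratio)


def chi2_pvalue(counts, expected):
    """Chi-square goodness of fit with pooling of low-expectation bins."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    order = np.argsort(expected)
    counts, expected = counts[order], expected[order]
    while expected.size > 2 and expected[0] < 5.0:
        expected[1] += expected[0]
        counts[1] += counts[0]
        expected, counts = expected[1:], counts[1:]
    expected *= counts.sum() / expected.sum()
    stat = np.sum((counts - expected) ** 2 / expected)
    return stats.chi2.sf(stat, df=expected.size - 1)
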