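import numpy as np
import pytest
from scipy import stats


@pytest.fixture(scope="session")
def slipknot_system():
    """Toy slipknot study system (chain, model, native multi-soliton)."""
    from knotfold.fixtures import toy_slipknot_system

    return toy_slipknot_system()


@pytest.fixture(scope="session")
def two_segment_decoy():
    """Decoy generated as the multi-soliton of a known two-segment model."""
    from knotfold.fixtures import toy_two_segment_model
    from knotfold.frenet import AngularConformation
    from knotfold.solver import relax_to_critical_point

    n = 24
    model = toy_two_segment_model(n)
    init = AngularConformation(np.full(n - 2, 1.3), np.zeros(n - 3))
    native = relax_to_critical_point(init, model, tol=1e-10)
    return model, native


def chi2_pvalue(counts, expected):
    """Chi-square goodness of fit with pooling of low-expectation bins."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    order = np.argsort(expected)
    counts, expected = counts[order], expected[order]
    # pool from the smallest-expectation end until every bin has >= 5 expected
    while expected.size > 2 and expected[0] < 5.0:
        expected[1] += expected[0]
        counts[1] += counts[0]
        expected, counts = expected[1:], counts[1:]
    expected *= counts.sum() / expected.sum()
    stat = np.sum((counts - expected) ** 2 / expected)
    return stats.chi2.sf(stat, df=expected.size - 1)
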