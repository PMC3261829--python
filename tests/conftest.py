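import numpy as np
import pytest

import equipoise as eq


@pytest.fixture(scope="session")
def scale7():
    return eq.make_scale(7)


@pytest.fixture(scope="session")
def heel_panels():
    """The four bundled heel-fracture cases (equipoise point 8/14)."""
    return eq.heel_fracture_panels()


@pytest.fixture(scope="session")
def heel_fits(heel_panels):
    """Per-case Beta fits for the bundled panels, computed once."""
    return {
        cid: eq.fit_case(heel_panels.for_case(cid), heel_panels.scale)
        for cid in heel_panels.case_ids
    }


def grid_search_beta(weights, midpoints, coarse_hi=100.0):
    """Independent MLE oracle: dense grid search of the weighted log-likelihood.

    Coarse pass over [1, coarse_hi] then successive refinements around the
    running optimum down to 1e-4 resolution.  Shares no code with the
    package optimiser.
    """
    from scipy import stats

    w = np.asarray(weights, float) / 100.0
    m = np.asarray(midpoints, float)

    def ll(a, b):
        grid = w * stats.beta.logpdf(m[None, None, :], a[:, :, None], b[:, :, None])
        return grid.sum(axis=-1)

    a = np.linspace(1.0, coarse_hi, 397)  # 0.25 spacing
    vals = ll(*np.meshgrid(a, a, indexing="ij"))
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    best = (a[i], a[j])
    for span in (0.5, 0.01):  # resolutions 0.005 then 1e-4
        aa = np.clip(np.linspace(best[0] - span, best[0] + span, 201), 1.0, None)
        bb = np.clip(np.linspace(best[1] - span, best[1] + span, 201), 1.0, None)
        vals = ll(*np.meshgrid(aa, bb, indexing="ij"))
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (aa[i], bb[j])
    return best
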