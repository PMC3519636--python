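import numpy as np
import pytest
from hypothesis import settings

import kvclamp as kc
from kvclamp.pipeline import PATCH_SOLUTIONS, SYMMETRIC_K

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nvshak1():
    return kc.load_fixture("NvShak1")


@pytest.fixture(scope="session")
def nvshak2():
    return kc.load_fixture("NvShak2")


@pytest.fixture(scope="session")
def nvshak4():
    return kc.load_fixture("NvShak4")


@pytest.fixture(scope="session")
def nvshak5():
    return kc.load_fixture("NvShak5")


@pytest.fixture(scope="session")
def patch_solutions():
    return PATCH_SOLUTIONS


@pytest.fixture(scope="session")
def symmetric_k():
    return SYMMETRIC_K


# ---------------------------------------------------------------------------
# Independent grid-search oracles (coarse grid + iterative refinement;
# no shared code with the fitting module)
# ---------------------------------------------------------------------------

def grid_boltzmann_oracle(v, g, n_refine=6):
    """Grid search over (v50, s) with linear least squares for (a1, a2)."""
    v = np.asarray(v, float)
    g = np.asarray(g, float)
    lo_v, hi_v = v.min() - 10, v.max() + 10
    lo_s, hi_s = 0.5, 25.0
    best = None
    for _ in range(n_refine):
        v50s = np.linspace(lo_v, hi_v, 41)
        ss = np.linspace(lo_s, hi_s, 41)
        for v50 in v50s:
            for s in ss:
                sig = 1.0 / (1.0 + np.exp((v - v50) / s))
                # g = a2 + (a1 - a2) sig = c0 + c1 sig
                A = np.column_stack([np.ones_like(sig), sig])
                coef, *_ = np.linalg.lstsq(A, g, rcond=None)
                rss = float(np.sum((A @ coef - g) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, v50, s, coef[0] + coef[1], coef[0])
        _, bv, bs, _, _ = best
        dv = (hi_v - lo_v) / 40
        ds = (hi_s - lo_s) / 40
        lo_v, hi_v = bv - 2 * dv, bv + 2 * dv
        lo_s, hi_s = max(bs - 2 * ds, 1e-3), bs + 2 * ds
    rss, v50, s, a1, a2 = best
    return {"v50": v50, "s": s, "a1": a1, "a2": a2, "rss": rss}


def grid_exponential_oracle(t, i, n_refine=6):
    """Grid search over tau with linear least squares for (i_i, a)."""
    t = np.asarray(t, float)
    i = np.asarray(i, float)
    tl = t - t[0]
    lo, hi = max(tl[1], 1e-4), 10 * tl[-1]
    best = None
    for _ in range(n_refine):
        for tau in np.geomspace(lo, hi, 200):
            e = np.exp(-tl / tau)
            A = np.column_stack([np.ones_like(e), e])
            coef, *_ = np.linalg.lstsq(A, i, rcond=None)
            rss = float(np.sum((A @ coef - i) ** 2))
            if best is None or rss < best[0]:
                best = (rss, tau, coef[0], coef[1])
        _, btau, _, _ = best
        lo, hi = btau / 1.3, btau * 1.3
    rss, tau, i_i, a = best
    return {"tau": tau, "i_i": i_i, "a": a, "rss": rss}
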