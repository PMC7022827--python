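import numpy as np
import pytest

from biosorb.kinetics import (
    TimeCourse,
    first_order_adsorbed,
    second_order_remaining,
)


@pytest.fixture
def first_order_tc():
    """Noiseless first-order time course (Ci=50, K1=0.052, Qe=0.91*Ci)."""
    times = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
    q = first_order_adsorbed(50.0, 0.052, times)
    return TimeCourse(
        initial_concentration=50.0, times=times, values=q[None, :],
        value_kind="adsorbed",
    )


@pytest.fixture
def second_order_tc():
    """Noiseless second-order time course (Ci=50, k2=0.0018)."""
    times = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
    ct = second_order_remaining(50.0, 0.0018, times)
    return TimeCourse(
        initial_concentration=50.0, times=times, values=ct[None, :],
        value_kind="remaining",
    )


def grid_search_rate(objective, lo=1e-6, hi=0.5, n_coarse=2000, n_refine=4001):
    """Brute-force one-parameter SSR minimiser, independent of scipy's
    optimisers: coarse grid then a fine sweep around the best cell."""
    grid = np.linspace(lo, hi, n_coarse)
    ssr = np.array([objective(k) for k in grid])
    i = int(np.argmin(ssr))
    lo2 = grid[max(i - 1, 0)]
    hi2 = grid[min(i + 1, n_coarse - 1)]
    fine = np.linspace(lo2, hi2, n_refine)
    ssr_f = np.array([objective(k) for k in fine])
    return float(fine[int(np.argmin(ssr_f))])
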