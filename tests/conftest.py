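"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rhodocycle import (
    GeneratorConfig,
    fit_multiexponential,
    gen_photocycle,
)
from rhodocycle.kinetics import SequentialScheme, expand_biphasic


def ode_occupancies(scheme: SequentialScheme, times: np.ndarray) -> np.ndarray:
    """Stiff-ODE oracle: numerically integrate the expanded first-order
    network and sum sub-state populations per original intermediate."""
    expanded = expand_biphasic(scheme)
    subs = [s for stage in expanded.stages for s in stage]
    index = {s.label: i for i, s in enumerate(subs)}
    n = len(subs)
    A = np.zeros((n, n))
    for si, stage in enumerate(expanded.stages):
        for s in stage:
            A[index[s.label], index[s.label]] = -s.rate
            if si + 1 < len(expanded.stages):
                for nxt in expanded.stages[si + 1]:
                    A[index[nxt.label], index[s.label]] += s.rate * nxt.entry_fraction
    y0 = np.zeros(n)
    for s in expanded.stages[0]:
        y0[index[s.label]] = s.entry_fraction
    t_eval = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda _t, y: A @ y,
        (0.0, t_eval[-1]),
        y0,
        t_eval=t_eval,
        method="Radau",
        rtol=1e-10,
        atol=1e-13,
    )
    assert sol.success
    return np.vstack(
        [
            sum(sol.y[index[lbl]] for lbl in expanded.mapping[state.label])
            for state in scheme.intermediates
        ]
    )


def grid_search_biexponential(times, Y, tau_lo, tau_hi, points_per_decade=200):
    """Exhaustive log-grid oracle for 2-exponential fits: for every ordered
    lifetime pair on the grid, solve the amplitudes by OLS and keep the
    lowest residual sum of squares.  Returns (tau_pair, amplitudes, rss)."""
    n_grid = int(np.ceil(np.log10(tau_hi / tau_lo) * points_per_decade)) + 1
    grid = np.geomspace(tau_lo, tau_hi, n_grid)
    E = np.exp(-times[:, None] / grid[None, :])  # (nt, G)
    G = E.T @ E
    B = E.T @ Y  # (G, n_wl)
    yty = float(np.sum(Y**2))
    best = (None, None, np.inf)
    for i in range(n_grid - 1):
        for j in range(i + 1, n_grid):
            M = np.array([[G[i, i], G[i, j]], [G[i, j], G[j, j]]])
            b = np.vstack([B[i], B[j]])  # (2, n_wl)
            try:
                a = np.linalg.solve(M, b)
            except np.linalg.LinAlgError:
                continue
            rss = yty - float(np.sum(a * b))
            if rss < best[2]:
                best = (np.array([grid[i], grid[j]]), a, rss)
    return best


@pytest.fixture(scope="session")
def sacr_dataset():
    """Seed-1 synthetic SacR photocycle dataset with its ground truth."""
    return gen_photocycle(GeneratorConfig(seed=1, scenario="sacr_photocycle"))


@pytest.fixture(scope="session")
def sacr_fit(sacr_dataset):
    data, _, _ = sacr_dataset
    return fit_multiexponential(data, 7, restarts=8)
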