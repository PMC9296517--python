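"""Global multi-exponential fitting of transient-absorption data.

All wavelengths share one set of time constants; per-wavelength amplitudes
(the decay-associated spectra, DAS) are solved linearly at each step by
ordinary least squares — the variable-projection trick — so the nonlinear
search runs only over log-lifetimes.  Multi-start initialisation guards
against local minima; uncertainties come from a residual-resampling
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import TransientDataset

__all__ = [
    "MultiExpFit",
    "BootstrapResult",
    "fit_multiexponential",
    "select_n_exponentials",
    "estimate_uncertainty",
]

#: convergence tolerance on the relative change of the residual sum of squares
RSS_TOL = 1e-10


@dataclass
class MultiExpFit:
    """Result of a global fit: shared lifetimes + per-wavelength amplitudes."""

    taus: np.ndarray  # ascending, seconds
    das: np.ndarray  # (n_wavelengths, n_exp) decay-associated spectra
    offset: np.ndarray | None  # per-wavelength constant, or None
    rss: float
    n_params: int
    n_points: int
    converged: bool
    wavelengths: np.ndarray
    times: np.ndarray
    tau_sd: np.ndarray | None = None
    das_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_exp(self) -> int:
        return int(self.taus.size)

    @property
    def bic(self) -> float:
        n = self.n_points
        return n * np.log(self.rss / n) + self.n_params * np.log(n)

    def design_matrix(self, times: np.ndarray | None = None) -> np.ndarray:
        return _design(self.times if times is None else times, self.taus,
                       self.offset is not None)

    def model(self, times: np.ndarray | None = None) -> np.ndarray:
        """Fitted dA matrix (n_wavelengths, n_times)."""
        E = self.design_matrix(times)
        amps = self.das if self.offset is None else np.hstack(
            [self.das, self.offset[:, None]]
        )
        return amps @ E.T

    def to_dict(self) -> dict:
        d = {
            "taus_s": self.taus.tolist(),
            "tau_sd_s": None if self.tau_sd is None else self.tau_sd.tolist(),
            "das": self.das.tolist(),
            "offset": None if self.offset is None else self.offset.tolist(),
            "wavelengths_nm": self.wavelengths.tolist(),
            "rss": float(self.rss),
            "bic": float(self.bic),
            "n_params": self.n_params,
            "n_points": self.n_points,
            "converged": bool(self.converged),
        }
        return d


@dataclass
class BootstrapResult:
    tau_sd: np.ndarray
    das_sd: np.ndarray
    tau_samples: np.ndarray  # (n_boot, n_exp)


def _design(times: np.ndarray, taus: np.ndarray, offset: bool) -> np.ndarray:
    E = np.exp(-times[:, None] / taus[None, :])
    if offset:
        E = np.hstack([E, np.ones((times.size, 1))])
    return E


def _solve_amplitudes(E: np.ndarray, Y: np.ndarray):
    """OLS amplitudes for fixed lifetimes. Y is (n_times, n_wavelengths)."""
    A, *_ = np.linalg.lstsq(E, Y, rcond=None)
    R = Y - E @ A
    return A, R


def _initial_taus(times: np.ndarray, n_exp: int, restarts: int,
                  init: np.ndarray | None, seed: int) -> list[np.ndarray]:
    t_lo = max(times[times > 0].min(), 1e-15)
    t_hi = times.max()
    base = np.geomspace(t_lo * 2.0, t_hi / 2.0, n_exp) if n_exp > 1 else np.array(
        [np.sqrt(t_lo * t_hi)]
    )
    inits = []
    if init is not None:
        inits.append(np.sort(np.asarray(init, dtype=float)))
    inits.append(base)
    rng = np.random.default_rng(seed)
    while len(inits) < restarts:
        inits.append(np.sort(base * rng.lognormal(0.0, 0.8, size=n_exp)))
    return inits[:restarts]


def fit_multiexponential(
    data: TransientDataset,
    n_exp: int,
    init: np.ndarray | None = None,
    restarts: int = 8,
    fit_offset: bool = False,
    seed: int = 0,
) -> MultiExpFit:
    """Fit ``dA(lambda,t) = sum_j DAS_j(lambda) exp(-t/tau_j) [+ offset]``.

    The lifetimes are optimised in log space (positivity, scale robustness)
    by trust-region least squares; amplitudes are projected out linearly.
    The best of ``restarts`` multi-starts is returned, lifetimes sorted
    ascending.  ``init`` seeds the first start.
    """
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    Y = data.delta_A.T  # (n_times, n_wl)
    if not np.all(np.isfinite(Y)):
        raise ValueError("data contains non-finite values")
    times = data.times
    if times.size < 3 * n_exp:
        raise ValueError(f"need >= {3 * n_exp} time points for n_exp={n_exp}")

    def residuals(log_taus: np.ndarray) -> np.ndarray:
        E = _design(times, np.exp(log_taus), fit_offset)
        _, R = _solve_amplitudes(E, Y)
        return R.ravel()

    best = None
    any_ok = False
    for start in _initial_taus(times, n_exp, max(restarts, 1), init, seed):
        try:
            sol = least_squares(
                residuals,
                np.log(start),
                method="trf",
                ftol=RSS_TOL,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=400 * n_exp,
            )
        except np.linalg.LinAlgError:  # pragma: no cover - pathological start
            continue
        any_ok = any_ok or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all multi-starts failed")

    taus = np.exp(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    E = _design(times, taus, fit_offset)
    A, R = _solve_amplitudes(E, Y)
    das = A[:n_exp].T  # (n_wl, n_exp)
    offset = A[n_exp].copy() if fit_offset else None
    rss = float(np.sum(R**2))
    n_wl = data.wavelengths.size
    n_params = n_exp + n_exp * n_wl + (n_wl if fit_offset else 0)
    return MultiExpFit(
        taus=taus,
        das=das,
        offset=offset,
        rss=rss,
        n_params=n_params,
        n_points=Y.size,
        converged=bool(any_ok),
        wavelengths=data.wavelengths.copy(),
        times=times.copy(),
        meta={"restarts": restarts, "seed": seed},
    )


def select_n_exponentials(
    data: TransientDataset,
    n_max: int,
    restarts: int = 8,
    fit_offset: bool = False,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick the number of exponentials by BIC over n = 1..n_max.

    BIC = N ln(rss/N) + k ln N with N data points and k free parameters.
    Each fit is seeded with the previous fit's lifetimes plus one extra
    (largest-log-gap midpoint), which also keeps rss non-increasing in n.
    Returns the chosen n and the full audit table.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rows = []
    fits: dict[int, MultiExpFit] = {}
    prev: MultiExpFit | None = None
    for n in range(1, n_max + 1):
        init = None
        if prev is not None:
            init = _insert_tau(prev.taus, data.times)
        fit = fit_multiexponential(
            data, n, init=init, restarts=restarts, fit_offset=fit_offset, seed=seed
        )
        if prev is not None and fit.rss > prev.rss:
            # nested-model guard: refit starting exactly from the augmented prev
            refit = fit_multiexponential(
                data, n, init=init, restarts=1, fit_offset=fit_offset, seed=seed
            )
            if refit.rss < fit.rss:
                fit = refit
        fits[n] = fit
        rows.append(
            {
                "n_exp": n,
                "rss": fit.rss,
                "n_params": fit.n_params,
                "bic": fit.bic,
                "converged": fit.converged,
                "taus_s": fit.taus.tolist(),
            }
        )
        prev = fit
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["bic"].idxmin(), "n_exp"])
    return chosen, table


def _insert_tau(taus: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Augment a lifetime set with the midpoint of its largest log gap."""
    log_t = np.log(
        np.concatenate([[max(times[times > 0].min(), 1e-15)], np.sort(taus),
                        [times.max()]])
    )
    gaps = np.diff(log_t)
    i = int(np.argmax(gaps))
    new = np.exp(0.5 * (log_t[i] + log_t[i + 1]))
    return np.sort(np.append(taus, new))


def estimate_uncertainty(
    fit: MultiExpFit,
    data: TransientDataset,
    n_boot: int = 200,
    seed: int = 0,
) -> BootstrapResult:
    """Residual-resampling bootstrap standard deviations of lifetimes and DAS.

    Residuals are resampled with replacement independently per wavelength,
    added back onto the fitted curves, and the model is refit from the
    original lifetimes.  Bootstrap lifetimes are matched to the originals by
    ascending rank.  Sets ``fit.tau_sd`` / ``fit.das_sd`` in place and also
    returns them.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    if not fit.converged:
        raise ValueError("refusing to bootstrap an unconverged fit")
    rng = np.random.default_rng(seed)
    model = fit.model()  # (n_wl, n_t)
    resid = data.delta_A - model
    n_wl, n_t = resid.shape
    fit_offset = fit.offset is not None
    tau_samples = np.empty((n_boot, fit.n_exp))
    das_samples = np.empty((n_boot, n_wl, fit.n_exp))
    for b in range(n_boot):
        idx = rng.integers(0, n_t, size=(n_wl, n_t))
        y_boot = model + np.take_along_axis(resid, idx, axis=1)
        boot_data = TransientDataset(
            data.wavelengths, data.times, y_boot, noise_sigma=data.noise_sigma
        )
        bfit = fit_multiexponential(
            boot_data,
            fit.n_exp,
            init=fit.taus,
            restarts=1,
            fit_offset=fit_offset,
            seed=seed,
        )
        tau_samples[b] = bfit.taus  # already ascending
        das_samples[b] = bfit.das
    result = BootstrapResult(
        tau_sd=tau_samples.std(axis=0, ddof=1),
        das_sd=das_samples.std(axis=0, ddof=1),
        tau_samples=tau_samples,
    )
    fit.tau_sd = result.tau_sd
    fit.das_sd = result.das_sd
    return result
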