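"""Retinal-reconstitution (regeneration) kinetics.

Apo-rhodopsin regains its visible absorption band as it binds all-trans-
retinal (ATR).  Two models are fitted to the absorbance time course:

one_step      apo --k--> holo
              A_lmax(t) = plateau * (1 - exp(-k t))

two_step      apo --k1--> X470 --k2--> holo
              the 470-nm channel follows the occupancy of the transient
              intermediate X470 (the pre-Schiff-base species), the lmax
              channel the holo occupancy of the two-step chain.

"Saturation" is quantified as t95, the time to reach 95% of the fitted
plateau — closed form ln(20)/k for one_step, root-solved on the fitted
curve for two_step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RegenerationTrace",
    "BindingFit",
    "fit_regeneration",
    "compare_kinetics",
    "select_binding_model",
]

SATURATION_LEVEL = 0.95


@dataclass
class RegenerationTrace:
    """Absorbance vs time from the moment of ATR addition."""

    times: np.ndarray  # s
    a_lambda_max: np.ndarray
    lambda_max: float  # nm
    a_470: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a_lambda_max = np.asarray(self.a_lambda_max, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if self.a_470 is not None:
            self.a_470 = np.asarray(self.a_470, dtype=float)
            if self.a_470.shape != self.times.shape:
                raise ValueError("a_470 length must match times")
        if self.a_lambda_max.shape != self.times.shape:
            raise ValueError("a_lambda_max length must match times")


@dataclass
class BindingFit:
    model: str  # "one_step" | "two_step"
    rate_constants: np.ndarray  # s^-1; (k,) or (k1, k2)
    plateau: float
    t95: float  # s
    rss: float
    n_points: int
    n_params: int
    converged: bool
    intermediate_peak_time: float | None = None  # two_step only
    intermediate_amplitude: float | None = None
    label: str = ""

    @property
    def bic(self) -> float:
        n = self.n_points
        return n * np.log(self.rss / n) + self.n_params * np.log(n)


def _chain_occupancies(t: np.ndarray, k1: float, k2: float):
    """Intermediate and product occupancies of apo -k1-> X -k2-> holo."""
    if abs(k1 - k2) < 1e-12 * max(k1, k2):
        k2 = k2 * (1.0 - 1e-9)
    x = k1 * (np.exp(-k2 * t) - np.exp(-k1 * t)) / (k1 - k2)
    holo = 1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)
    return x, holo


def _t95_two_step(k1: float, k2: float) -> float:
    level = SATURATION_LEVEL
    hi = 10.0 / min(k1, k2)
    lo = 1e-12 / max(k1, k2)
    f = lambda t: _chain_occupancies(np.array([t]), k1, k2)[1][0] - level
    while f(hi) < 0:  # pragma: no cover - generous bracket
        hi *= 10
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-13)


def fit_regeneration(trace: RegenerationTrace, model: str = "one_step") -> BindingFit:
    """Nonlinear least-squares fit of a regeneration trace.

    For ``two_step`` the 470-nm channel, when recorded, is fitted jointly
    with the lmax channel (shared rate constants, its own amplitude).
    """
    if model not in ("one_step", "two_step"):
        raise ValueError(f"unknown model {model!r}")
    t = trace.times
    y = trace.a_lambda_max
    if t.size < 8:
        raise ValueError("need at least 8 time points")

    plateau0 = float(max(y.max(), 1e-12))
    # crude initial rate from the half-rise time
    half = np.argmax(y >= 0.5 * plateau0)
    t_half = t[half] if y[half] >= 0.5 * plateau0 and t[half] > 0 else t[-1] / 4
    k0 = np.log(2.0) / max(t_half, t[t > 0].min() if (t > 0).any() else 1.0)

    params = lmfit.Parameters()
    params.add("plateau", value=plateau0, min=0.0)
    if model == "one_step":
        params.add("k", value=k0, min=1e-12)

        def resid(p):
            return y - p["plateau"] * (1.0 - np.exp(-p["k"] * t))

    else:
        params.add("k1", value=3.0 * k0, min=1e-12)
        params.add("k2", value=k0, min=1e-12)
        fit_470 = trace.a_470 is not None
        if fit_470:
            params.add("amp470", value=float(np.nanmax(trace.a_470)), min=0.0)

        def resid(p):
            x, holo = _chain_occupancies(t, p["k1"].value, p["k2"].value)
            r = y - p["plateau"] * holo
            if fit_470:
                r = np.concatenate([r, trace.a_470 - p["amp470"] * x])
            return r

    out = lmfit.minimize(resid, params, method="leastsq")
    p = out.params
    converged = bool(out.success)
    if not converged:
        warnings.warn(f"regeneration fit did not converge for {trace.label!r}")
    rss = float(np.sum(np.asarray(out.residual) ** 2))

    if model == "one_step":
        k = float(p["k"].value)
        rates = np.array([k])
        t95 = np.log(1.0 / (1.0 - SATURATION_LEVEL)) / k
        peak_time = peak_amp = None
    else:
        k1, k2 = float(p["k1"].value), float(p["k2"].value)
        rates = np.array([k1, k2])
        t95 = _t95_two_step(k1, k2)
        peak_time = (
            np.log(k1 / k2) / (k1 - k2)
            if abs(k1 - k2) > 1e-12 * max(k1, k2)
            else 1.0 / k1
        )
        peak_amp = float(p["amp470"].value) if trace.a_470 is not None else None
    return BindingFit(
        model=model,
        rate_constants=rates,
        plateau=float(p["plateau"].value),
        t95=float(t95),
        rss=rss,
        n_points=int(np.asarray(out.residual).size),
        n_params=len(params),
        converged=converged,
        intermediate_peak_time=peak_time,
        intermediate_amplitude=peak_amp,
        label=trace.label,
    )


def select_binding_model(trace: RegenerationTrace) -> tuple[BindingFit, dict]:
    """Fit both binding models and keep the lower-BIC one."""
    fits = {m: fit_regeneration(trace, m) for m in ("one_step", "two_step")}
    bics = {m: f.bic for m, f in fits.items()}
    best = min(bics, key=bics.get)
    return fits[best], bics


def compare_kinetics(fits: list[BindingFit]) -> dict:
    """Rank converged fits by t95 (fastest first) with pairwise fold-changes."""
    usable = [f for f in fits if f.converged]
    if len(usable) < len(fits):
        warnings.warn(
            f"excluding {len(fits) - len(usable)} unconverged fit(s) from ranking"
        )
    if len(usable) < 2:
        raise ValueError("need at least 2 converged fits to compare")
    order = sorted(usable, key=lambda f: f.t95)
    fold = {
        (a.label or f"fit{ia}", b.label or f"fit{ib}"): b.t95 / a.t95
        for ia, a in enumerate(order)
        for ib, b in enumerate(order)
        if ib > ia
    }
    return {
        "ranking": [f.label or f"fit{i}" for i, f in enumerate(order)],
        "t95_s": [f.t95 for f in order],
        "fold_change_t95": {f"{a}->{b}": v for (a, b), v in fold.items()},
    }
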