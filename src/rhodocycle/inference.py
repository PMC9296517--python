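"""From a global multi-exponential fit to a sequential photocycle.

A unidirectional chain whose state lifetimes equal the fitted time constants
reproduces any sum-of-exponentials signal exactly: the chain occupancies are
themselves sums of the same exponentials (Bateman), so the decay-associated
spectra (DAS) and the per-intermediate evolution-associated difference
spectra (EADS) are related by an invertible linear map.  Adjacent components
whose EADS are (near-)identical are then merged into single intermediates
with biphasic decay, recovering the lifetimes *and* branching fractions of
the underlying photocycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .globalfit import MultiExpFit
from .kinetics import (
    DEGENERACY_EPS,
    IntermediateState,
    SequentialScheme,
    concentrations,
)

__all__ = [
    "PhotocycleResult",
    "das_to_eads",
    "merge_biphasic",
    "refine_scheme",
    "label_intermediates",
    "infer_photocycle",
]

#: default probe-wavelength conventions for spectroscopic labelling (nm)
DEFAULT_CONVENTIONS = {"blue": 406.0, "bleach": 561.0, "red": 638.0}


@dataclass
class PhotocycleResult:
    """Inferred sequential photocycle with per-intermediate spectra."""

    scheme: SequentialScheme
    eads: np.ndarray  # (n_wavelengths, n_states)
    wavelengths: np.ndarray
    times: np.ndarray
    labels: list[str] | None = None  # spectroscopic names once assigned
    diagnostics: dict = field(default_factory=dict)

    def reconstruct(self, times: np.ndarray | None = None) -> np.ndarray:
        """dA implied by (scheme, EADS) on the given time grid."""
        t = self.times if times is None else times
        occ, _ = concentrations(self.scheme, t)
        return self.eads @ occ

    def to_dict(self) -> dict:
        states = []
        for i, s in enumerate(self.scheme.intermediates):
            states.append(
                {
                    "label": s.label,
                    "spectroscopic_label": None if self.labels is None else self.labels[i],
                    "lifetimes_s": list(s.lifetimes),
                    "fractions_pct": None
                    if s.fractions is None
                    else [100.0 * f for f in s.fractions],
                    "eads": {
                        f"{w:g}": float(v)
                        for w, v in zip(self.wavelengths, self.eads[:, i])
                    },
                }
            )
        return {"states": states, "diagnostics": self.diagnostics}


def bateman_coefficients(taus: np.ndarray) -> np.ndarray:
    """Matrix B with ``c_i(t) = sum_j B[i, j] exp(-t / tau_j)`` for the
    unidirectional chain whose i-th state has lifetime ``taus[i]`` (chain
    order as given, unit population in state 0 at t=0)."""
    taus = np.asarray(taus, dtype=float)
    n = taus.size
    k = 1.0 / taus
    rel_gap = np.abs(k[:, None] - k[None, :]) / np.maximum(k[:, None], k[None, :])
    np.fill_diagonal(rel_gap, 1.0)
    if np.any(rel_gap < DEGENERACY_EPS):
        raise ValueError("duplicate lifetimes: DAS->EADS map is degenerate")
    B = np.zeros((n, n))
    for i in range(n):
        ks = k[: i + 1]
        pref = np.prod(ks[:-1]) if i > 0 else 1.0
        for j in range(i + 1):
            denom = np.prod(np.delete(ks, j) - ks[j]) if i > 0 else 1.0
            B[i, j] = pref / denom
    return B


def das_to_eads(fit: MultiExpFit) -> PhotocycleResult:
    """Evolution-associated difference spectra of the sequential chain whose
    state lifetimes are the fitted time constants (ascending).

    Solves ``DAS = EADS @ B`` for EADS, where B holds the Bateman
    sum-of-exponential coefficients of the chain occupancies; the two
    representations reconstruct identical signals.
    """
    if not fit.converged:
        warnings.warn("fit flagged unconverged; EADS may be unreliable")
    taus = fit.taus
    if np.any(np.diff(taus) < 0):
        raise ValueError("fitted lifetimes must be ascending")
    B = bateman_coefficients(taus)
    eads = np.linalg.solve(B.T, fit.das.T).T  # (n_wl, n)
    scheme = SequentialScheme(
        intermediates=tuple(
            IntermediateState(label=_roman(i + 1), lifetimes=(tau,))
            for i, tau in enumerate(taus)
        )
    )
    result = PhotocycleResult(
        scheme=scheme,
        eads=eads,
        wavelengths=fit.wavelengths.copy(),
        times=fit.times.copy(),
        diagnostics={"rss": fit.rss, "taus_s": taus.tolist()},
    )
    recon_err = float(
        np.max(np.abs(result.reconstruct() - fit.model()))
    )
    result.diagnostics["reconstruction_max_abs_err"] = recon_err
    return result


_ROMANS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _roman(i: int) -> str:
    return _ROMANS[i - 1] if i <= len(_ROMANS) else str(i)


def _pairings(n: int, m: int) -> list[tuple[int, ...]]:
    """All ways to choose m disjoint adjacent index pairs (i, i+1) from 0..n-1;
    each pairing is the tuple of left indices."""
    out: list[tuple[int, ...]] = []

    def rec(start: int, chosen: tuple[int, ...]) -> None:
        if len(chosen) == m:
            out.append(chosen)
            return
        for i in range(start, n - 1):
            rec(i + 2, chosen + (i,))

    rec(0, ())
    return out


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def merge_biphasic(result: PhotocycleResult, max_states: int) -> PhotocycleResult:
    """Merge adjacent chain components into biphasic intermediates.

    The components to merge are the disjoint adjacent pairs with the highest
    summed EADS cosine similarity (spectrally identical sub-populations of
    one intermediate look alike).  Branching fractions — the share of
    molecules routed through each sub-lifetime — are then fitted by least
    squares on the branched-chain occupancies against the fitted signal, with
    the merged state's spectra shared between its sub-states.
    """
    n = result.scheme.n_states
    n_merge = n - max_states
    if n_merge <= 0:
        raise ValueError(f"nothing to merge: {n} components, max_states={max_states}")
    if n_merge > n // 2:
        raise ValueError(
            f"cannot perform {n_merge} disjoint adjacent merges on {n} components"
        )
    taus = np.array([s.lifetimes[0] for s in result.scheme.intermediates])
    sims = [
        _cosine(result.eads[:, i], result.eads[:, i + 1]) for i in range(n - 1)
    ]
    best_pairing = max(
        _pairings(n, n_merge), key=lambda pairing: sum(sims[i] for i in pairing)
    )
    merged_left = set(best_pairing)

    # target signal: noiseless reconstruction of the fit itself
    target = result.reconstruct()

    def build_scheme(fracs: np.ndarray) -> SequentialScheme:
        states, fi, i = [], 0, 0
        while i < n:
            if i in merged_left:
                # fractions live in the open interval; a boundary optimum
                # (one sub-path carrying everything) is clipped
                f = float(np.clip(fracs[fi], 1e-6, 1.0 - 1e-6))
                states.append(
                    IntermediateState(
                        label=_roman(len(states) + 1),
                        lifetimes=(taus[i], taus[i + 1]),
                        fractions=(f, 1.0 - f),
                    )
                )
                fi += 1
                i += 2
            else:
                states.append(
                    IntermediateState(label=_roman(len(states) + 1),
                                      lifetimes=(taus[i],))
                )
                i += 1
        return SequentialScheme(intermediates=tuple(states))

    def objective(x: np.ndarray) -> float:
        fracs = 1.0 / (1.0 + np.exp(-x))  # logit -> (0,1)
        occ, _ = concentrations(build_scheme(fracs), result.times)
        S, *_ = np.linalg.lstsq(occ.T, target.T, rcond=None)
        return float(np.sum((target - S.T @ occ) ** 2))

    best = None
    for x0_val in (-1.0, 0.0, 1.0):
        sol = minimize(
            objective,
            np.full(n_merge, x0_val),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
        )
        if best is None or sol.fun < best.fun:
            best = sol
    fracs = 1.0 / (1.0 + np.exp(-best.x))
    scheme = build_scheme(fracs)
    occ, _ = concentrations(scheme, result.times)
    S, *_ = np.linalg.lstsq(occ.T, target.T, rcond=None)
    eads = S.T  # (n_wl, max_states)
    merged = PhotocycleResult(
        scheme=scheme,
        eads=eads,
        wavelengths=result.wavelengths.copy(),
        times=result.times.copy(),
        diagnostics={
            **result.diagnostics,
            "merged_pairs": sorted(merged_left),
            "merge_similarities": sims,
            "merge_rss": float(best.fun),
        },
    )
    return merged


def refine_scheme(result: PhotocycleResult, data) -> PhotocycleResult:
    """Refit the inferred scheme's lifetimes and branching fractions to data.

    The merged sequential model constrains a biphasic intermediate's two
    sub-populations to share one difference spectrum, so it has far fewer
    free amplitudes than the unconstrained multi-exponential fit.  Refitting
    the structural model directly (lifetimes in log space, fractions through
    a logistic map, spectra projected out linearly) tightens the slow,
    spectrally overlapped components in particular.
    """
    scheme = result.scheme
    states = scheme.intermediates
    Y = data.delta_A
    t = data.times
    n_life = sum(len(s.lifetimes) for s in states)
    x0 = np.concatenate(
        [
            np.log([tau for s in states for tau in s.lifetimes]),
            [np.log(s.fractions[0] / s.fractions[1]) for s in states if s.biphasic],
        ]
    )

    def unpack(x: np.ndarray) -> SequentialScheme:
        lifetimes = np.exp(x[:n_life])
        fracs = np.clip(1.0 / (1.0 + np.exp(-x[n_life:])), 1e-6, 1.0 - 1e-6)
        out, li, fi = [], 0, 0
        for s in states:
            m = len(s.lifetimes)
            taus = tuple(sorted(lifetimes[li : li + m]))
            if m == 2:
                # keep the fraction attached to the faster lifetime
                f = fracs[fi] if lifetimes[li] <= lifetimes[li + 1] else 1 - fracs[fi]
                out.append(IntermediateState(s.label, taus, (f, 1.0 - f)))
                fi += 1
            else:
                out.append(IntermediateState(s.label, taus))
            li += m
        return SequentialScheme(intermediates=tuple(out))

    def residuals(x: np.ndarray) -> np.ndarray:
        occ, _ = concentrations(unpack(x), t)
        S, *_ = np.linalg.lstsq(occ.T, Y.T, rcond=None)
        return (Y - S.T @ occ).ravel()

    sol = least_squares(residuals, x0, method="trf", ftol=1e-12, xtol=1e-12,
                        gtol=1e-12, max_nfev=2000)
    scheme = unpack(sol.x)
    occ, _ = concentrations(scheme, t)
    S, *_ = np.linalg.lstsq(occ.T, Y.T, rcond=None)
    return PhotocycleResult(
        scheme=scheme,
        eads=S.T,
        wavelengths=result.wavelengths.copy(),
        times=t.copy(),
        diagnostics={
            **result.diagnostics,
            "refined": True,
            "refine_rss": float(2 * sol.cost),
        },
    )


def label_intermediates(
    result: PhotocycleResult,
    conventions: dict[str, float] | None = None,
) -> PhotocycleResult:
    """Assign spectroscopic names from three-probe EADS signatures.

    * dominant positive amplitude at the blue probe -> ``M`` (deprotonated
      Schiff base);
    * dominant positive amplitude at the red probe -> ``K`` for the earliest
      such state, ``O`` for later ones;
    * early states (before M) with no dominant positive band -> ``L``: a
      state absorbing close to the dark maximum shows mostly bleach at the
      probes;
    * anything else keeps its ordinal name; an all-zero spectrum warns.

    "Dominant" means positive and at least half the largest probe amplitude
    in magnitude.
    """
    conv = dict(DEFAULT_CONVENTIONS if conventions is None else conventions)
    for key in ("blue", "bleach", "red"):
        if key not in conv:
            raise ValueError(f"conventions must define a {key!r} wavelength")
    idx = {}
    for key, w in conv.items():
        hits = np.flatnonzero(np.isclose(result.wavelengths, w, rtol=0, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"convention wavelength {w} nm absent from EADS grid")
        idx[key] = int(hits[0])

    n = result.scheme.n_states
    channels = np.vstack(
        [result.eads[idx[k], :] for k in ("blue", "bleach", "red")]
    )  # (3, n_states)
    raw = [None] * n
    for i in range(n):
        col = channels[:, i]
        if np.allclose(col, 0.0, atol=1e-12):
            warnings.warn(f"state {i + 1}: all-zero EADS at probe wavelengths")
            raw[i] = "zero"
            continue
        j = int(np.argmax(col))
        if col[j] > 0.0 and col[j] >= 0.5 * np.max(np.abs(col)):
            raw[i] = ("M", "bleach_pos", "red")[j]
        else:
            raw[i] = "no_band"

    red_states = [i for i in range(n) if raw[i] == "red"]
    m_states = [i for i in range(n) if raw[i] == "M"]
    first_m = m_states[0] if m_states else (n + 1) // 2
    labels = []
    for i in range(n):
        if raw[i] == "M":
            labels.append("M")
        elif raw[i] == "red":
            labels.append("K" if i == red_states[0] and i < n - 1 else "O")
        elif raw[i] in ("no_band", "bleach_pos") and i < first_m:
            labels.append("L")
        else:
            labels.append(_roman(i + 1))
    result.labels = labels
    return result


def infer_photocycle(
    fit: MultiExpFit,
    max_states: int | None = None,
    conventions: dict[str, float] | None = None,
    data=None,
) -> PhotocycleResult:
    """Convenience pipeline: DAS -> EADS, optional biphasic merge, optional
    refinement against the data, spectroscopic labelling."""
    result = das_to_eads(fit)
    if max_states is not None and max_states < fit.n_exp:
        result = merge_biphasic(result, max_states)
    if data is not None:
        result = refine_scheme(result, data)
    return label_intermediates(result, conventions)
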