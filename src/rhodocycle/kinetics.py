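"""Forward kinetic model of a sequential rhodopsin photocycle.

After a single-turnover flash, a microbial rhodopsin traverses an ordered
chain of spectrally distinct intermediates (K, L, M, N, O ... or simply
I, II, ...) and finally recovers the dark state.  Each intermediate decays
irreversibly into the next with first-order kinetics; an intermediate whose
decay is double-exponential ("biphasic") is modelled as two parallel,
spectrally identical sub-populations entered with fixed branching fractions.

Occupancies of such a unidirectional first-order chain have the classical
Bateman closed form — sums of exponentials in the chain's decay rates — which
this module evaluates directly, so the forward signal

    dA(lambda, t) = sum_i  d_eps_i(lambda) * c_i(t)

is an explicit multi-exponential in time.  That structure is what the global
fitting stage exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IntermediateState",
    "SequentialScheme",
    "DifferenceSpectrum",
    "TransientDataset",
    "SubState",
    "ExpandedChain",
    "expand_biphasic",
    "concentrations",
    "forward_signal",
]

#: relative gap below which two chain rates are considered degenerate
DEGENERACY_EPS = 1e-9


@dataclass(frozen=True)
class IntermediateState:
    """One photocycle intermediate.

    Parameters
    ----------
    label:
        Name of the state (e.g. ``"I"`` .. ``"V"`` or ``"K"``, ``"M"``).
    lifetimes:
        One or two positive decay lifetimes in seconds.  Two lifetimes mean
        the state decays biphasically.
    fractions:
        Branching weights matching ``lifetimes``; required iff the state is
        biphasic.  Each in (0, 1), summing to 1.
    """

    label: str
    lifetimes: tuple[float, ...]
    fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        lifetimes = tuple(float(t) for t in self.lifetimes)
        object.__setattr__(self, "lifetimes", lifetimes)
        if not 1 <= len(lifetimes) <= 2:
            raise ValueError(
                f"state {self.label!r}: need 1 or 2 lifetimes, got {len(lifetimes)}"
            )
        if any(t <= 0 or not np.isfinite(t) for t in lifetimes):
            raise ValueError(f"state {self.label!r}: lifetimes must be positive")
        if len(lifetimes) == 2:
            if self.fractions is None:
                raise ValueError(f"biphasic state {self.label!r} needs fractions")
            fractions = tuple(float(f) for f in self.fractions)
            object.__setattr__(self, "fractions", fractions)
            if len(fractions) != 2 or any(not (0.0 < f < 1.0) for f in fractions):
                raise ValueError(
                    f"state {self.label!r}: fractions must be two values in (0,1)"
                )
            if abs(sum(fractions) - 1.0) > 1e-9:
                raise ValueError(f"state {self.label!r}: fractions must sum to 1")
        elif self.fractions is not None:
            raise ValueError(f"monophasic state {self.label!r} takes no fractions")

    @property
    def biphasic(self) -> bool:
        return len(self.lifetimes) == 2


@dataclass(frozen=True)
class SequentialScheme:
    """Ordered photocycle: each intermediate decays only into the next.

    The last intermediate decays into the recovered dark state
    (``recovery_target``).
    """

    intermediates: tuple[IntermediateState, ...]
    recovery_target: str = "dark"

    def __post_init__(self) -> None:
        states = tuple(self.intermediates)
        object.__setattr__(self, "intermediates", states)
        if not states:
            raise ValueError("scheme needs at least one intermediate")
        labels = [s.label for s in states]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate state labels: {labels}")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.intermediates]

    @property
    def n_states(self) -> int:
        return len(self.intermediates)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "recovery_target": self.recovery_target,
            "intermediates": [
                {
                    "label": s.label,
                    "lifetimes_s": list(s.lifetimes),
                    **({"fractions": list(s.fractions)} if s.fractions else {}),
                }
                for s in self.intermediates
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SequentialScheme":
        states = tuple(
            IntermediateState(
                label=s["label"],
                lifetimes=tuple(s["lifetimes_s"]),
                fractions=tuple(s["fractions"]) if s.get("fractions") else None,
            )
            for s in d["intermediates"]
        )
        return cls(intermediates=states, recovery_target=d.get("recovery_target", "dark"))

    @classmethod
    def from_json(cls, path) -> "SequentialScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class DifferenceSpectrum:
    """Per-intermediate difference spectra on a fixed wavelength grid.

    ``delta_epsilon[i, k]`` is the absorbance of intermediate *i* minus the
    dark-state absorbance at wavelength ``wavelengths[k]`` (arbitrary units).
    Recovered dark-state molecules contribute zero by construction, so the
    bleach of the initial state appears as negative values near its band.
    """

    wavelengths: np.ndarray
    delta_epsilon: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        de = np.atleast_2d(np.asarray(self.delta_epsilon, dtype=float))
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "delta_epsilon", de)
        if de.shape != (len(self.labels), wl.size):
            raise ValueError(
                f"delta_epsilon shape {de.shape} != (n_states={len(self.labels)},"
                f" n_wavelengths={wl.size})"
            )

    def column_indices(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Exact grid lookup (no interpolation); unknown wavelength is an error."""
        idx = []
        for w in wavelengths:
            hits = np.flatnonzero(np.isclose(self.wavelengths, w, rtol=0, atol=1e-9))
            if hits.size == 0:
                raise ValueError(f"wavelength {w} nm not on the spectrum grid")
            idx.append(hits[0])
        return np.asarray(idx, dtype=int)


@dataclass
class TransientDataset:
    """Flash-induced absorbance-change matrix dA(lambda, t)."""

    wavelengths: np.ndarray
    times: np.ndarray
    delta_A: np.ndarray
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.delta_A = np.atleast_2d(np.asarray(self.delta_A, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.delta_A.shape != (self.wavelengths.size, self.times.size):
            raise ValueError(
                f"delta_A shape {self.delta_A.shape} != "
                f"({self.wavelengths.size}, {self.times.size})"
            )
        if not np.all(np.isfinite(self.delta_A)):
            raise ValueError("delta_A contains non-finite values")

    # -- long-format CSV round trip ---------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        wl = np.repeat(self.wavelengths, self.times.size)
        tt = np.tile(self.times, self.wavelengths.size)
        df = pd.DataFrame(
            {"wavelength_nm": wl, "time_s": tt, "delta_A": self.delta_A.ravel()}
        )
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, noise_sigma: float = 0.0, meta: dict | None = None):
        import pandas as pd

        df = pd.read_csv(path)
        wl = np.unique(df["wavelength_nm"].to_numpy())
        times = np.unique(df["time_s"].to_numpy())
        mat = (
            df.pivot_table(index="wavelength_nm", columns="time_s", values="delta_A")
            .loc[wl, times]
            .to_numpy()
        )
        return cls(wl, times, mat, noise_sigma=noise_sigma, meta=meta or {})


# ---------------------------------------------------------------------------
# biphasic expansion


@dataclass(frozen=True)
class SubState:
    """One kinetic sub-population of the expanded chain."""

    label: str
    parent: str
    rate: float  # 1/lifetime, s^-1
    entry_fraction: float  # branching probability on entry into the parent


@dataclass(frozen=True)
class ExpandedChain:
    """Branched first-order network: stages in chain order, each stage one or
    two parallel sub-states of an original intermediate."""

    stages: tuple[tuple[SubState, ...], ...]
    mapping: dict  # original label -> tuple of sub-state labels

    @property
    def sub_labels(self) -> list[str]:
        return [s.label for stage in self.stages for s in stage]


def expand_biphasic(scheme: SequentialScheme) -> ExpandedChain:
    """Replace each biphasic intermediate by two parallel, spectrally
    identical sub-states entered with its branching fractions.

    The result is a branched network of first-order steps: every sub-state of
    stage *i* decays into stage *i+1*, splitting according to that stage's
    entry fractions (the last stage decays to the dark state).
    """
    stages: list[tuple[SubState, ...]] = []
    mapping: dict[str, tuple[str, ...]] = {}
    for state in scheme.intermediates:
        if len(state.lifetimes) > 2:  # unreachable via the dataclass, belt+braces
            raise ValueError(f"state {state.label!r}: more than 2 lifetimes")
        if state.biphasic:
            subs = tuple(
                SubState(f"{state.label}_{suffix}", state.label, 1.0 / tau, frac)
                for suffix, tau, frac in zip(
                    ("a", "b"), state.lifetimes, state.fractions
                )
            )
        else:
            subs = (
                SubState(state.label, state.label, 1.0 / state.lifetimes[0], 1.0),
            )
        stages.append(subs)
        mapping[state.label] = tuple(s.label for s in subs)
    return ExpandedChain(stages=tuple(stages), mapping=mapping)


# ---------------------------------------------------------------------------
# Bateman closed form


def _separate_rates(rates: np.ndarray) -> np.ndarray:
    """Nudge near-degenerate rates apart so Bateman denominators stay finite.

    Whenever two rates differ by less than ``DEGENERACY_EPS`` relative, the
    smaller is shrunk by ``DEGENERACY_EPS`` relative; repeated until all
    pairwise gaps are resolved.
    """
    k = np.array(rates, dtype=float)
    for _ in range(8 * k.size):
        clashed = False
        for i in range(k.size):
            for j in range(i + 1, k.size):
                scale = max(abs(k[i]), abs(k[j]))
                if abs(k[i] - k[j]) < DEGENERACY_EPS * scale:
                    small = i if k[i] <= k[j] else j
                    k[small] *= 1.0 - DEGENERACY_EPS
                    clashed = True
        if not clashed:
            break
    return k


def bateman_terminal(rates: Sequence[float], times: np.ndarray) -> np.ndarray:
    """Occupancy of the last state of the linear chain ``k1 -> k2 -> ... -> kn``
    with unit population in state 1 at t=0 (Bateman solution)."""
    k = _separate_rates(np.asarray(rates, dtype=float))
    t = np.asarray(times, dtype=float)
    n = k.size
    if n == 1:
        return np.exp(-k[0] * t)
    out = np.zeros_like(t)
    prefactor = np.prod(k[:-1])
    for i in range(n):
        denom = np.prod(np.delete(k, i) - k[i])
        out += np.exp(-k[i] * t) / denom
    return prefactor * out


def _expanded_occupancies(
    expanded: ExpandedChain, times: np.ndarray, excitation: float = 1.0
) -> dict[str, np.ndarray]:
    """Occupancy of every sub-state, summing over all branch paths that reach it."""
    t = np.asarray(times, dtype=float)
    occ = {lbl: np.zeros_like(t) for lbl in expanded.sub_labels}

    def walk(stage_idx: int, prefix_rates: list[float], prob: float) -> None:
        if stage_idx == len(expanded.stages):
            return
        for sub in expanded.stages[stage_idx]:
            rates = prefix_rates + [sub.rate]
            p = prob * sub.entry_fraction
            occ[sub.label] += p * bateman_terminal(rates, t)
            walk(stage_idx + 1, rates, p)

    walk(0, [], excitation)
    return occ


def concentrations(
    scheme: SequentialScheme,
    times: Iterable[float],
    excitation: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-dependent occupancies of every intermediate after a flash.

    At t=0 the flash places an ``excitation`` fraction (default 1: full
    single-turnover) of the molecules in the first intermediate (split over
    its sub-states if biphasic); everything else is in the dark state.

    Returns
    -------
    occupancies : ndarray, shape (n_states, n_times)
        Occupancy of each original intermediate (biphasic sub-states summed).
    recovered : ndarray, shape (n_times,)
        Population that has returned to the dark state,
        ``excitation - occupancies.sum(axis=0)``.
    """
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                   dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    expanded = expand_biphasic(scheme)
    sub_occ = _expanded_occupancies(expanded, t, excitation=excitation)
    occ = np.vstack(
        [
            np.sum([sub_occ[lbl] for lbl in expanded.mapping[state.label]], axis=0)
            for state in scheme.intermediates
        ]
    )
    recovered = excitation - occ.sum(axis=0)
    return occ, recovered


def forward_signal(
    scheme: SequentialScheme,
    spectra: DifferenceSpectrum,
    wavelengths: Sequence[float],
    times: Iterable[float],
    excitation: float = 1.0,
) -> TransientDataset:
    """Noiseless transient-absorption signal of a scheme.

    ``dA(lambda, t) = sum_i d_eps_i(lambda) * c_i(t)``; the dark state carries
    zero difference spectrum, so the signal decays to zero on full recovery.
    Wavelengths must be members of the spectrum grid (exact lookup).
    """
    if list(spectra.labels) != scheme.labels:
        raise ValueError(
            f"spectrum labels {list(spectra.labels)} do not match scheme "
            f"{scheme.labels}"
        )
    cols = spectra.column_indices(wavelengths)
    occ, _ = concentrations(scheme, times, excitation=excitation)
    de = spectra.delta_epsilon[:, cols]  # (n_states, n_wl)
    delta_A = de.T @ occ  # (n_wl, n_times)
    return TransientDataset(
        wavelengths=np.asarray(wavelengths, dtype=float),
        times=np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                         dtype=float),
        delta_A=delta_A,
        noise_sigma=0.0,
        meta={"source": "forward_signal", "scheme": scheme.to_dict()},
    )
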