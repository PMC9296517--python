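"""Seeded generators for every input class of the pipeline.

Each scenario emulates the statistical structure its consuming analysis
stage assumes — multi-exponential transient absorption with additive
Gaussian noise, first-order pH dynamics with a leak term, chain-model
regeneration traces, and proteome FASTA sets with planted homologs — and
emits machine-readable ground truth alongside the data.  One integer seed
drives one root generator; independent sub-streams are derived per scenario
so the modules stay decoupled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    DifferenceSpectrum,
    IntermediateState,
    SequentialScheme,
    TransientDataset,
    forward_signal,
)
from .pump import PumpTrace
from .reconstitution import RegenerationTrace, _chain_occupancies
from .screen import load_pathway_exemplars, load_reference

__all__ = [
    "GeneratorConfig",
    "sacr_scheme",
    "sacr_spectra",
    "gen_photocycle",
    "gen_pump_pair",
    "gen_reconstitution",
    "gen_proteomes",
    "gen_sample_panel",
]

PROBE_WAVELENGTHS = (406.0, 561.0, 638.0)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
AA_FREQ = np.array(
    [.0777, .0157, .0530, .0656, .0405, .0691, .0227, .0591, .0595, .0960,
     .0238, .0427, .0469, .0393, .0526, .0694, .0550, .0667, .0118, .0311]
)
AA_FREQ = AA_FREQ / AA_FREQ.sum()


@dataclass
class GeneratorConfig:
    seed: int
    scenario: str
    overrides: dict = field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        # per-scenario sub-stream: mixes the root seed with the scenario name
        return np.random.default_rng(
            [int(self.seed), zlib.crc32(self.scenario.encode())]
        )

    def get(self, key, default):
        return self.overrides.get(key, default)


# ---------------------------------------------------------------------------
# photocycle


def sacr_scheme() -> SequentialScheme:
    """Five-intermediate SacR photocycle with the measured lifetimes:
    I biphasic 1.7/13 µs (42/58%), II 118 µs, III 1.6 ms, IV 23.5 ms,
    V biphasic 98.4/384 ms (56/44%)."""
    return SequentialScheme(
        intermediates=(
            IntermediateState("I", (1.7e-6, 13e-6), (0.42, 0.58)),
            IntermediateState("II", (118e-6,)),
            IntermediateState("III", (1.6e-3,)),
            IntermediateState("IV", (23.5e-3,)),
            IntermediateState("V", (98.4e-3, 384e-3), (0.56, 0.44)),
        )
    )


def _gauss(wl, center, sigma=45.0):
    wl = np.asarray(wl, dtype=float)
    return np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))


def sacr_spectra(
    wavelengths=PROBE_WAVELENGTHS,
    dark_center: float = 550.0,
) -> DifferenceSpectrum:
    """Ground-truth difference spectra at the probe wavelengths.

    Each intermediate carries a Gaussian absorption band minus the dark-state
    band at 550 nm (SacR absorption maximum): I red-shifted K-like (590 nm),
    II L-like (540 nm), III blue-shifted M-like (410 nm, deprotonated Schiff
    base), IV N-like (575 nm), V O-like (630 nm).  The Gaussian lineshape is
    a generator convenience, not a fitted model.
    """
    wl = np.asarray(wavelengths, dtype=float)
    dark = _gauss(wl, dark_center)
    bands = [
        (1.00, 590.0),  # I  (K-like)
        (0.90, 540.0),  # II (L-like)
        (1.00, 410.0),  # III (M)
        (1.05, 575.0),  # IV (N-like)
        (0.90, 630.0),  # V  (O-like)
    ]
    de = np.vstack([amp * _gauss(wl, c) - dark for amp, c in bands])
    return DifferenceSpectrum(
        wavelengths=wl, delta_epsilon=de, labels=("I", "II", "III", "IV", "V")
    )


def gen_photocycle(config: GeneratorConfig):
    """Synthetic three-wavelength transient-absorption dataset.

    Defaults: 200 log-spaced time points over 1 µs–10 s, probes at
    406/561/638 nm, i.i.d. Gaussian noise with sigma = 1% of max |dA|.

    Returns (TransientDataset, ground-truth SequentialScheme,
    ground-truth DifferenceSpectrum).
    """
    rng = config.rng()
    scheme = config.get("scheme", sacr_scheme())
    wavelengths = np.asarray(config.get("wavelengths", PROBE_WAVELENGTHS), float)
    n_times = int(config.get("n_times", 200))
    t_min = float(config.get("t_min", 1e-6))
    t_max = float(config.get("t_max", 10.0))
    noise_frac = float(config.get("noise_frac", 0.01))
    if noise_frac < 0:
        raise ValueError("noise fraction must be >= 0")
    spectra = config.get("spectra", sacr_spectra(wavelengths))
    times = np.geomspace(t_min, t_max, n_times)
    clean = forward_signal(scheme, spectra, wavelengths, times)
    sigma = noise_frac * np.max(np.abs(clean.delta_A))
    noisy = clean.delta_A + rng.normal(0.0, sigma, size=clean.delta_A.shape) \
        if sigma > 0 else clean.delta_A.copy()
    data = TransientDataset(
        wavelengths=wavelengths,
        times=times,
        delta_A=noisy,
        noise_sigma=float(sigma),
        meta={
            "seed": config.seed,
            "scenario": "sacr_photocycle",
            "noise_frac": noise_frac,
            "scheme": scheme.to_dict(),
        },
    )
    return data, scheme, spectra


# ---------------------------------------------------------------------------
# pump assay


def gen_pump_pair(config: GeneratorConfig):
    """Matched (test, CCCP-control) pH traces.

    pH dynamics: dpH/dt = -r L(t) + g (pH0 - pH), Euler-integrated at the
    sampling rate; the CCCP trace multiplies the leak g by ``cccp_leak_factor``
    (default 50), collapsing the light-driven pH change.  Defaults: 600 s at
    1 Hz, light on 150–450 s, r = 3.3e-4 pH/s, g = 5e-3 s^-1, observation
    noise sigma = 2e-3 pH.
    """
    rng = config.rng()
    duration = float(config.get("duration_s", 600.0))
    dt = 1.0 / float(config.get("rate_hz", 1.0))
    on = float(config.get("light_on_s", 150.0))
    off = float(config.get("light_off_s", 450.0))
    ph0 = float(config.get("ph0", 7.0))
    r = float(config.get("pump_rate", 3.3e-4))  # pH/s under light
    g = float(config.get("leak", 5e-3))  # s^-1 relaxation to ph0
    cccp_factor = float(config.get("cccp_leak_factor", 50.0))
    noise = float(config.get("noise_ph", 2e-3))

    times = np.arange(0.0, duration + dt / 2, dt)

    def integrate(leak):
        ph = np.empty_like(times)
        ph[0] = ph0
        for i in range(1, times.size):
            light = 1.0 if on <= times[i - 1] < off else 0.0
            dph = -r * light + leak * (ph0 - ph[i - 1])
            ph[i] = ph[i - 1] + dph * dt
        return ph

    test_ph = integrate(g) + rng.normal(0.0, noise, size=times.size)
    cccp_ph = integrate(g * cccp_factor) + rng.normal(0.0, noise, size=times.size)
    meta = {"seed": config.seed, "pump_rate": r, "leak": g,
            "cccp_leak_factor": cccp_factor, "noise_ph": noise}
    test = PumpTrace(times, test_ph, (on, off), cccp=False,
                     label="test", meta=meta)
    control = PumpTrace(times, cccp_ph, (on, off), cccp=True,
                        label="cccp", meta=meta)
    return test, control


# ---------------------------------------------------------------------------
# reconstitution

#: defaults giving t95 ~= 15 s (SacR-like two-step) and ~30 min (GR-like one-step)
SACR_K1, SACR_K2 = 0.5, 0.24  # s^-1
GR_K = np.log(20.0) / 1800.0  # s^-1


def gen_reconstitution(config: GeneratorConfig):
    """SacR-like (two-step, transient 470-nm channel) or GR-like (one-step)
    regeneration trace with Gaussian noise (default 0.5% of plateau).

    ``config.scenario`` selects ``reconstitution_sacr`` or
    ``reconstitution_gr``.  Returns (RegenerationTrace, truth dict).
    """
    rng = config.rng()
    noise_frac = float(config.get("noise_frac", 0.005))
    plateau = float(config.get("plateau", 0.5))
    sigma = noise_frac * plateau
    if config.scenario == "reconstitution_gr":
        k = float(config.get("k", GR_K))
        times = np.arange(0.0, float(config.get("duration_s", 5400.0)) + 1e-9,
                          float(config.get("dt_s", 10.0)))
        clean = plateau * (1.0 - np.exp(-k * times))
        trace = RegenerationTrace(
            times=times,
            a_lambda_max=clean + rng.normal(0.0, sigma, times.size),
            lambda_max=float(config.get("lambda_max", 539.0)),
            label="GR",
            meta={"seed": config.seed},
        )
        truth = {"model": "one_step", "k": k, "plateau": plateau,
                 "t95_s": np.log(20.0) / k}
        return trace, truth
    k1 = float(config.get("k1", SACR_K1))
    k2 = float(config.get("k2", SACR_K2))
    amp470 = float(config.get("amp470", 0.3)) * plateau
    times = np.arange(0.0, float(config.get("duration_s", 120.0)) + 1e-9,
                      float(config.get("dt_s", 0.5)))
    x, holo = _chain_occupancies(times, k1, k2)
    trace = RegenerationTrace(
        times=times,
        a_lambda_max=plateau * holo + rng.normal(0.0, sigma, times.size),
        a_470=amp470 * x + rng.normal(0.0, sigma, times.size),
        lambda_max=float(config.get("lambda_max", 550.0)),
        label="SacR",
        meta={"seed": config.seed},
    )
    truth = {"model": "two_step", "k1": k1, "k2": k2, "plateau": plateau,
             "amp470": amp470,
             "intermediate_peak_time_s": np.log(k1 / k2) / (k1 - k2)}
    return trace, truth


# ---------------------------------------------------------------------------
# sequences


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(AA, size=length, p=AA_FREQ))


def _mutate(rng, seq: str, identity: float) -> str:
    """Point-substitute residues down to the requested fractional identity."""
    seq = list(seq)
    n_mut = int(round((1.0 - identity) * len(seq)))
    for i in rng.choice(len(seq), size=n_mut, replace=False):
        choices = AA[AA != seq[i]]
        seq[i] = rng.choice(choices)
    return "".join(seq)


def _shuffled(rng, seq: str) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def make_rhodopsin_variant(substitutions: dict[int, str] | None = None) -> str:
    """BR scaffold with substitutions at 1-based mature-BR positions.

    ``{96: "S"}`` yields the DTS-motif fixture (D85/T89 retained, D96S)."""
    _, br = load_reference()
    seq = list(br)
    for pos, res in (substitutions or {}).items():
        seq[pos - 1] = res
    return "".join(seq)


def make_c_subunit(kind: str) -> str:
    """H+- or Na+-type c-subunit fixture from the packaged reference.

    The reference itself carries the full Na+ quartet (Q27/E60/S61/T62);
    the H+ fixture breaks the quartet but keeps the E60 carboxylate."""
    _, ref = load_reference("c_subunit_reference_synthetic.fasta")
    if kind == "Na_plus":
        return ref
    if kind == "H_plus":
        seq = list(ref)
        seq[26] = "F"  # Q27F
        seq[60] = "A"  # S61A
        seq[61] = "I"  # T62I
        return "".join(seq)
    raise ValueError(f"unknown c-subunit kind {kind!r}")


def gen_proteomes(config: GeneratorConfig):
    """Proteome FASTA set with a scored truth table.

    Builds per-proteome protein dicts seeded with exact or mutated pathway
    exemplars (well-separated ~70% identity for mutants), shuffled-exemplar
    decoys, and random background proteins.  Default panel:

    * ``saccharibacteria`` — rhodopsin (DTS variant) only, no blh/crt;
    * ``actinobacteria`` — blh + all four crt genes (mutated copies) and a
      rhodopsin;
    * ``decoy`` — shuffled copies of every exemplar, nothing real.

    Returns (proteomes: name -> {protein_id: seq}, truth: DataFrame,
    fixtures: dict with rhodopsin/c-subunit fixtures).
    """
    rng = config.rng()
    refs = load_pathway_exemplars()
    mut_identity = float(config.get("mutant_identity", 0.7))
    n_background = int(config.get("n_background", 10))

    panel = config.get(
        "panel",
        {
            "saccharibacteria": {"rhodopsin": "variant"},
            "actinobacteria": {
                "blh": "mutant", "crtE": "mutant", "crtB": "mutant",
                "crtI": "mutant", "crtY": "mutant", "rhodopsin": "exact",
            },
            "decoy": {gene: "shuffled" for gene in refs},
        },
    )

    proteomes: dict[str, dict[str, str]] = {}
    truth_rows = []
    for name, plan in panel.items():
        prot: dict[str, str] = {}
        for i in range(n_background):
            prot[f"{name}_bg{i}"] = _random_protein(rng, int(rng.integers(120, 350)))
        for gene, mode in plan.items():
            ex_id, ex_seq = refs[gene]
            if mode == "exact":
                seq = ex_seq
            elif mode == "mutant":
                seq = _mutate(rng, ex_seq, mut_identity)
            elif mode == "variant":  # rhodopsin with the DTS pump motif
                seq = make_rhodopsin_variant({96: "S"})
            elif mode == "shuffled":
                seq = _shuffled(rng, ex_seq)
            else:
                raise ValueError(f"unknown plant mode {mode!r}")
            prot[f"{name}_{gene}_{mode}"] = seq
        proteomes[name] = prot
        row = {"genome_id": name}
        for gene in refs:
            mode = plan.get(gene)
            row[f"{gene}_present"] = mode in ("exact", "mutant", "variant")
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    fixtures = {
        "rhodopsin_dts": make_rhodopsin_variant({96: "S"}),
        "rhodopsin_dtd": make_rhodopsin_variant(),
        "c_subunit_H": make_c_subunit("H_plus"),
        "c_subunit_Na": make_c_subunit("Na_plus"),
    }
    return proteomes, truth, fixtures


def gen_sample_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Per-sample blh-carrier rows shaped like the freshwater-lake panel.

    Defaults: 15 samples, 14 with at least one blh-encoding entry, carriers
    predominantly (90%) labelled Actinobacteria.
    """
    rng = config.rng()
    n_samples = int(config.get("n_samples", 15))
    n_positive = int(config.get("n_positive_samples", min(14, n_samples)))
    p_actino = float(config.get("p_actinobacteria", 0.9))
    max_carriers = int(config.get("max_carriers", 5))

    positive = rng.choice(n_samples, size=n_positive, replace=False)
    rows = []
    for s in range(n_samples):
        sample = f"lake_{s + 1:02d}"
        n_carriers = int(rng.integers(1, max_carriers + 1)) if s in positive else 0
        n_rows = max(n_carriers, int(rng.integers(1, 4)))
        for j in range(n_rows):
            has_blh = j < n_carriers
            taxon = (
                "Actinobacteria"
                if (has_blh and rng.random() < p_actino)
                else rng.choice(["Proteobacteria", "Bacteroidetes", "Cyanobacteria"])
            )
            rows.append(
                {
                    "sample": sample,
                    "genome_id": f"{sample}_scaffold{j}",
                    "taxon": str(taxon),
                    "blh_present": bool(has_blh),
                }
            )
    return pd.DataFrame(rows)


def write_fasta(proteome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
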