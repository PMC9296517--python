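# Methods

## Sequential photocycle model

The forward model is a strictly unidirectional first-order chain: each
intermediate decays only into the next, the last into the recovered dark
state, and a flash places the whole excited population (default excitation
fraction 1.0; partial excitation is an overall scale absorbed into the
difference spectra) into the first intermediate at t = 0. No back-reactions
or inter-state equilibria are modelled. An intermediate with biphasic decay
is represented as two *parallel, spectrally identical sub-populations*
entered with fixed branching fractions; the expanded network is a small
branched chain whose occupancies are evaluated per path with the Bateman
closed form (sums of exponentials in the path's decay rates).

Numerical notes:

* **Near-degenerate rates.** Bateman denominators contain pairwise rate
  differences. When two rates in a path differ by less than 1e-9 relative,
  the smaller is shrunk by 1e-9 relative before evaluation. This removes the
  0/0 at exact degeneracy at the cost of ~1e-7 accuracy right at the
  degenerate point (float cancellation in e^(−k₁t) − e^(−k₂t)); for
  generically separated rates the closed form agrees with stiff ODE
  integration to better than 1e-6 relative (tested on randomized chains of
  up to 7 states spanning six decades of lifetime).
* **Spectra on a fixed grid.** Difference spectra are defined per wavelength
  with exact-membership lookup, no interpolation, so the fit target is
  unambiguous.

## Global fitting (variable projection)

All wavelengths share one lifetime set; amplitudes are profiled out by
ordinary least squares inside the residual function, and a trust-region
least-squares search runs over log-lifetimes (positivity, scale
robustness). Multi-start defaults: 8 restarts, first start log-spaced
across the data's time span, later starts log-normally jittered
(deterministic internal seeding). Convergence: 1e-10 relative change of the
residual sum of squares. Offsets are off by default (full recovery
assumed) and switchable for drifting baselines. Fitted lifetimes are
reported ascending; model order can be chosen by BIC
(N·ln(rss/N) + k·ln N), where each n is additionally seeded with the
previous fit's lifetimes plus the midpoint of their largest log-gap — this
also guarantees rss is non-increasing in n. Uncertainties come from a
residual-resampling bootstrap (per-wavelength resampling, refit from the
fitted lifetimes, rank matching; default 200 replicates).

## From DAS to a photocycle

For a unidirectional chain whose state lifetimes equal the fitted time
constants, occupancies are linear combinations of the same exponentials
(coefficient matrix B), so DAS = EADS·B and EADS = DAS·B⁻¹; both
representations reconstruct the identical signal (checked to 1e-8).
Duplicate lifetimes make B singular and are rejected. For the two-state
chain with τ₁ ≪ τ₂ this reduces to EADS₁ = DAS₁ + DAS₂ and
EADS₂ = DAS₂·(1 − τ₁/τ₂), which the occupancy least-squares oracle in the
test suite confirms.

**Merging.** Biphasic intermediates are recovered by merging adjacent
components: among all sets of disjoint adjacent pairs, the set with the
highest summed EADS cosine similarity is merged (sub-populations of one
intermediate share a spectrum, so their chain-EADS look alike; enumeration
is exact for the small component counts involved). Branching fractions —
the share of molecules routed through each sub-lifetime, i.e. entry flux in
the branched representation — are then fitted (logistic-mapped, clipped to
the open interval) with the state spectra solved linearly on the branched
occupancies.

**Refinement.** The merged structural model constrains each biphasic state
to one shared spectrum, which removes about a third of the free amplitude
parameters relative to the unconstrained multi-exponential fit. A final
least-squares pass over (log-lifetimes, fractions) with spectra projected
out, started from the merge result, therefore tightens the slow, spectrally
overlapped components noticeably; it is applied whenever the data are
available to the inference step.

**Labelling** uses the three-probe convention (blue 406 nm, bleach 561 nm,
red 638 nm): a state whose dominant positive band (positive and ≥ half the
largest probe amplitude in magnitude) is blue is M; red-dominant states are
K (earliest) or O; remaining pre-M states with no dominant positive band
are L (absorbing near the dark maximum, they show mostly bleach); anything
else keeps its ordinal name.

Whether the original measurement fitted n exponentials and merged, or
fitted a branched model directly, is not knowable from the figure; the
fit-then-merge-then-refine route is this package's modelling choice and is
flagged as such.

## Pump assay

Baseline = mean pH over the final 10 s before light-on; ΔpH = pH at
light-off minus baseline; initial rate = least-squares slope over the first
20% of the window; direction requires |ΔpH| > 3 pre-light standard
deviations. The outward-H⁺-pump call requires acidification plus a CCCP
control retaining < 0.2 of the response — the 0.2 operationalises "almost
eliminated", is exposed as a parameter, and raising it can only preserve a
positive call. Decreasing external pH = outward pumping (the assay's stated
orientation). No smoothing by default; an optional moving median is
available for noisy traces. ΔpH is not converted to proton flux (buffer
capacity is not part of the inputs).

## Reconstitution

One-step binding has the closed form t95 = ln(20)/k; the two-step chain
(apo → 470-nm species → holo) uses the chain solution for the λmax channel,
the intermediate occupancy for the 470-nm channel (idealization: the
intermediate absorbs only at 470 nm, the holoprotein only at λmax), the
analytic peak time ln(k₁/k₂)/(k₁−k₂), and root-solving for t95 on the
fitted curve. Saturation = 95% of the fitted plateau (configurable; the
source observation states "saturated" without a criterion). The transient
470-nm species is modelled on-pathway; whether it is on-pathway or parallel
is not established. Fits use Levenberg–Marquardt via lmfit with half-rise
initialisation.

## Genome screens

Pairwise alignment throughout (BLOSUM62, gap open 11 / extend 1, fixed in
config): semi-global (free terminal gaps) for position mapping against the
packaged mature-bacteriorhodopsin scaffold — conventional mature numbering
D85/T89/D96 — and local for pathway screening (present iff best identity
≥ 30% over ≥ 50% exemplar coverage; conservative defaults, not calibrated
claims; raising thresholds can only remove hits). The c-subunit rule table
(Na⁺ iff the full Q/E/S/T quartet at reference positions 27/60/61/62,
else H⁺ iff a carboxylate at 60, else unclassified) is a documented
reconstruction of the standard diagnostic and is user-overridable; the
reference c subunit and the blh/crt exemplars are synthetic fixtures
(labelled as such), and deliberately no HMM/profile databases are used.

## Synthetic data

Generator defaults define the study conditions:

* **Photocycle**: the measured five-state scheme (biphasic 1.7/13 µs at
  42/58%, 118 µs, 1.6 ms, 23.5 ms, biphasic 98.4/384 ms at 56/44%), probes
  406/561/638 nm, 200 log-spaced points over 1 µs–10 s, Gaussian noise with
  σ = 1% of max |ΔA|. Ground-truth difference spectra are Gaussian bands
  (σ = 45 nm) minus the 550-nm dark band, with intermediate maxima at
  590 (K-like), 540 (L-like), 410 (M), 575 (N-like) and 630 nm (O-like) —
  a generic rhodopsin-like layout chosen once so that every chain rate has
  measurable amplitude at some probe; the Gaussian lineshape is a generator
  convenience, not a fitted model.
* **Pump**: dpH/dt = −r·L(t) + g·(pH₀ − pH), 600 s at 1 Hz, light 150–450 s,
  r = 3.3e-4 pH/s, leak g = 5e-3 s⁻¹, CCCP multiplies g by 50, observation
  noise 2e-3 pH. Illumination length and sampling rate of the real assay
  are not printed anywhere; these are declared fixtures.
* **Reconstitution**: SacR-like two-step k₁ = 0.5, k₂ = 0.24 s⁻¹
  (t95 ≈ 15 s) with a 470-nm channel at 0.3× plateau; GR-like one-step
  k = ln 20/1800 s⁻¹ (t95 = 30 min); noise 0.5% of plateau. These are
  fixtures consistent with, not read from, the reported saturation times.
* **Sequences**: proteomes of random background proteins (typical amino-acid
  composition) with planted exact or 70%-identity copies of the exemplars
  and residue-shuffled decoys; identities are well separated by
  construction, which is why screen accuracy against the emitted truth
  table is exactly 100% at default thresholds. The sample panel defaults to
  15 samples, 14 blh-positive, carriers 90% Actinobacteria-labelled.

One root integer seed drives everything; per-scenario sub-streams (seed
mixed with a scenario hash) decouple the modules. Text outputs use 9
significant digits for byte-stable regeneration.

What passing on synthetic data does **not** show: the generators draw
i.i.d. Gaussian noise on exact model curves, so they cannot expose
instrument-response convolution, correlated drift, baseline artefacts,
spectral overlap beyond the assumed lineshapes, or real-genome homology
structure (paralogs, domain shuffling, compositional bias). Results on real
data depend on those factors and on the unidirectional-chain assumption
itself.

## Problem sizes

Default analyses are desk-scale: 600-point global fits (seconds), 20-seed
recovery studies (~10 s), 100-scheme ODE cross-checks (~30 s),
100-replicate model-selection studies (seconds), and alignment screens over
tens of proteins (seconds).
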