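# Methods

This note documents the models, estimators and synthetic-data generators in
`nartools`, the numerical choices behind them, and what validation on
synthetic data does and does not establish.

## Photocurrent model and feature extraction

A pump photocurrent under a light pulse is summarized by three quantities:
the peak current density *I*ₚ, the steady-state density *I*ss at the end of
the pulse, and the inactivation ratio (*I*ₚ − *I*ss)/*I*ₚ. Densities are
currents divided by whole-cell capacitance (pA/pF), which removes cell-size
dependence; outward pump current is positive by convention.

`extract_features` takes *I*ₚ as the in-epoch maximum of a 1-kHz zero-phase
low-pass copy of the trace (4th-order Butterworth, `sosfiltfilt`) so that a
single noisy sample cannot set the peak; recordings from typical patch-clamp
hardware are already band-limited near 1 kHz, so on real data the filter is
nearly transparent. Note that a mathematically discontinuous step (possible
only in synthetic data) excites ~6% ringing in a zero-phase filter; the
filter can be disabled (`peak_filter_hz=None`) for such inputs. *I*ss is the
mean over a terminal window before light-off, 50 ms by default: the window
length is a free choice — a short terminal mean is noise-robust and unbiased
once inactivation has equilibrated (the slowest generator kinetics leave
< 0.01% residual relaxation over the last 50 ms of a 1-s pulse). A steady
estimate pushed below zero by noise is clamped to 0 with a warning, which
keeps the inactivation ratio in [0, 1].

## Irradiance–response models

Single-photon photochemistry predicts Michaelis–Menten (rectangular
hyperbola) saturation of photocurrent with irradiance, *y* = *I*max·*x*/(*x*
+ *K*_D). Some pumps additionally show power-dependent suppression of the
steady-state current above a threshold irradiance *T*; the composite model
subtracts a second hyperbola in the excess irradiance (*x* − *T*), engaged
only for *x* > *T*, and is exactly continuous at the threshold. *T* is a
protocol constant (10 mW/mm² by default), not a fitted parameter: fitting a
free threshold on 7-point protocols is badly conditioned and the threshold
is established by the experimental design.

Both fitters use `scipy.optimize.least_squares` (trust-region reflective)
with physical bounds — amplitudes in [0, 10 × max response], Michaelis
constants in [10⁻³, 10⁴] mW/mm² — and multi-start initialization (*K*_D
started at the half-response irradiance and at the median irradiance;
for the composite model a 2 × 2 grid over both constants), keeping the best
converged solution. Tolerances are set near machine precision so noiseless
model data are recovered to ≤ 10⁻⁶ relative error. Degenerate inputs are
flagged rather than hidden: a constant response drives *K*_D to its lower
bound and sets `at_boundary`; a fitted composite that dips below zero
anywhere on the data range sets `negative_model_values` instead of clamping.

The restricted-range fit (`fit_kd_restricted`, default ≤ 12 mW/mm²) exists
because a suppressed steady-state response only follows the plain hyperbola
on its low-irradiance branch; the fit records how many points were excluded.
Fits are per cell, summarized as mean ± SEM across cells
(`summarize_fits`); a pooled fit can be obtained by concatenating cells.

## Voltage dependence and action spectrum

I–V series are normalized to the 0 mV value (exactly 1 at 0 mV afterwards;
the operation is idempotent and scale-invariant). *S*neg is the OLS slope
over the non-positive-voltage points, reported in 10⁻³ mV⁻¹ — normalized
currents change by ~0.3 over 80 mV, so slopes of order a few × 10⁻³ per mV
are the natural scale. The 0 mV anchor is included in the regression by
default (`include_zero=False` is available): on exactly linear data the
choice is immaterial, and on noisy data the anchor stabilizes the intercept.

Action spectra divide *I*ss at each stimulus wavelength by the irradiance
delivered at that wavelength (power density, mW/mm², as delivered by the
light engine; a photon-flux correction would additionally weight by λ and is
deliberately not applied), normalize each cell to its own maximum, then
average across cells — so per-cell expression level cancels exactly and the
SEM reflects shape variability only.

## Overlapping index

Reporter and membrane-marker profiles are taken along the horizontal and
vertical pixel lines through the cell centroid (supplied, or computed as the
marker intensity centroid). Each profile pair is trimmed to the marker's
membrane extent: scanning inward from each end, the first sample at which
the marker reaches half of its global maximum. Within those bounds, the
Pearson correlation between reporter and shifted marker is computed at lags
0, ±1, ±2, ±3 pixels (positive lag moves the marker toward higher indices;
non-overlapping ends are dropped — wraparound would spuriously correlate
opposite membrane edges). The index is the arithmetic mean of the 14
coefficients (7 lags × 2 axes).

Per-lag Pearson normalization (rather than an unnormalized sliding dot
product) is what bounds every coefficient — and hence the index — in
[−1, 1] and makes the index invariant to positive affine rescaling of
either channel. Swapping the channels maps the lag-*k* coefficient to the
lag-(−*k*) coefficient and leaves the mean unchanged. One caveat inherent in
the definition: even perfectly co-localized profiles give an index below
+1.0, because the nonzero-lag terms are autocorrelations of a non-constant
profile, which are generically < 1; +1.0 is a ceiling, not an attainable
value for smooth unimodal profiles (identical Gaussian-like pairs score
~0.85). At the default 0.133 µm pixel pitch the maximal lag spans ~0.4 µm; a
warning is issued if the configured pitch puts lag 3 more than 25% away from
that reference distance.

## Silencing analysis

Spikes are detected as upward crossings of −10 mV separated by at least
2 ms; the threshold sits far from both synaptic noise and spike overshoot,
so crossing times are insensitive to its exact value. Spike counts are
binned into uniform 1-s zones per sweep; zone rate is the mean count across
sweeps. Light/Dark firing ratios are computed over three windows — before
(0–1 s), during (1–11 s), after (11–12 s) illumination by default; an
alternative window set treating the 2-s zone as light onset is provided
(`ALT_WINDOWS`) since protocols differ in where onset falls within the first
zone. A zero dark-window denominator yields NaN (flagged), never a
fabricated ratio.

Zone-wise and group comparisons use exact rank tests implemented in
`nartools.stats`. For combined sample sizes ≤ 25, the Mann–Whitney null is
computed by dynamic-programming subset-sum counting over the pooled midranks
(equivalent to enumerating all C(n₁+n₂, n₁) assignments, without doing so
explicitly), and the Wilcoxon signed-rank null by counting over all 2^m sign
patterns; doubled ranks keep midrank sums integral. Two-sided p doubles the
smaller tail, capped at 1. Above the exact limit, a normal approximation
with midrank tie correction and continuity correction is used. Zero
differences in the signed-rank test are discarded; all-zero differences are
a degeneracy error, not p = 1.

## Transport classification and flux bound

The pH slope of an illuminated E. coli suspension is estimated by OLS over
the central 80% of the illumination epoch (avoiding onset/offset
transients), minus the pre-light baseline slope, in pH/min; signs are called
with a ±0.005 pH/min dead-band. The decision table: alkalinization with Na⁺
present that CCCP *enhances* (secondary H⁺ uptake driven by electrogenic
export of another cation) plus acidification without Na⁺ that CCCP
*diminishes* (primary H⁺ pumping) classifies a sodium pump; CCCP-diminished
acidification with Na⁺ present classifies a proton pump; anything else is
inconclusive, with the Na₂SO₄ condition optionally confirming anion
independence. "Enhances/diminishes" means a ≥ 25% relative slope change
(with matching sign, or a flip toward zero) — a quantitative stand-in for a
qualitative judgement, configurable at the call.

`flux_ratio_bound` is exact interval arithmetic: with intracellular Na⁺
activity exceeding H⁺ activity ~320,000-fold (≈10 mM Na⁺ at pH 7.3) and an
H⁺/Na⁺ uptake rate-constant ratio of 8,000–9,000, the H⁺ flux fraction is
bounded by 2.50–2.81%, i.e. strictly under 3%. The bound is homogeneous of
degree zero: rescaling both ratios by a common factor leaves it unchanged.

## Chimera construction

Apoproteins are partitioned into seven contiguous TMD segments whose
concatenation reproduces the parent exactly. Chimeras follow the published
junction coordinates literally (1-based inclusive): the N-terminal donor
contributes residues 1 through its TMD-*k* end (52, 100, 127, 160, 192, 234
for the IaNaR-side boundary set) and the C-terminal acceptor resumes at its
stated start (54, 102, 129, 162, 194, 236 for the KR2-side set), so one
acceptor residue is skipped at each join — an alignment-offset artifact of
the two parents' numbering that we reproduce rather than "repair", since the
expressed constructs used exactly these ranges. Every IaNaR→KR2 chimera is
therefore 279 residues long. When both parents share TMD3 exactly, the
junction-2 and junction-3 chimeras are identical proteins — a property the
synthetic parent generator reproduces and the tests assert.

## Synthetic-data generators

All generators are deterministic functions of (parameters, seed) using
`numpy.random.default_rng`. Defaults encode the study conditions: 1-s light
pulses at up to 99 mW/mm² on the irradiance grid {1, 3, 6, 12, 25, 50, 99};
I–V grids at −80…0 mV in 20 mV steps; 549 nm/2.6 mW/mm² 10-s illumination
inside a 12-s current injection for silencing runs; 0.133 µm pixel pitch
soma images.

* **Photocurrents**: rise (1 − e^(−t/τ_act)) to the peak density, relaxation
  toward the steady level with τ_inact gated to start at 7 τ_act (so the
  attained peak matches the nominal amplitude to < 0.1%), deactivation with
  τ_deact after light-off; additive Gaussian noise in density units. Default
  τ of 5/100/10 ms at 10 kHz reproduce the characteristic trace shape; no
  photocycle kinetics are modelled.
* **Dose–response**: exact hyperbola (optionally suppression-modified)
  times (1 + cv·N(0,1)) multiplicative noise, per cell.
* **I–V**: 1 + slope·V with optional additive noise (re-normalize before
  slope estimation when noisy).
* **Soma images**: marker ring with Gaussian radial cross-section (FWHM =
  membrane width); reporter either the co-localized ring, interior
  aggregates (a central blob plus two random interior blobs, guaranteeing
  signal variance on both centroid axes), or a weighted mix; additive noise
  clipped at zero.
* **Silencing sweeps**: inhomogeneous Poisson spike times (piecewise-
  constant rate: baseline / silenced / 1-s rebound segments) thinned to a
  5-ms minimum separation, rendered as 2-ms triangular +80 mV events on a
  baseline that is depolarized during injection and hyperpolarized during
  light. The thinning biases realized rates down by ≈ rate × 5 ms (≈ 5% at
  10 Hz), which the rate-recovery tests account for. Only crossing times
  matter downstream; this is not a conductance-based neuron model.
* **pH traces**: flat baseline, linear drift during illumination (+0.04
  pH/min for NaCl/Na₂SO₄, ×2 with CCCP; −0.03 pH/min for KCl, ×0.2 with
  CCCP — magnitudes chosen to give the ~0.1 pH excursions typical of these
  suspension assays), value held after light-off.
* **Parent sequences**: random 279/280-residue amino-acid strings sharing
  TMD3 exactly; synthetic stand-ins for the real accessions, sufficient for
  every coordinate-level property of chimera construction.

## What synthetic validation shows — and does not

Passing the round-trip suites establishes that every estimator is a
consistent inverse of its generating model at realistic noise levels, that
the exact tests match full enumeration, and that the overlap index obeys its
bounds and symmetries on arbitrary profiles. It does not establish
performance on pathologies the generators omit: seal-leak drift and series-
resistance error in recordings, out-of-focus light and shot noise in
confocal images, bursting or adapting firing patterns, or multi-phasic pH
responses. Analysis-window defaults (steady window, ratio windows, slope
dead-band) are configurable precisely because real protocols vary.

## Problem sizes

Stochastic recovery checks use 200 replicates per curve (noise CV 5%),
1,000 fuzzed profile pairs for the index bounds, 200–400 sweeps for
Poisson-rate recovery, and exhaustive enumeration up to combined n = 10 for
the rank-test oracles; these sizes give comfortable margins on every
tolerance while keeping the full suite under a minute of compute.
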