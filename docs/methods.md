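# Methods

This note documents the models, numerical choices and known limitations of
each analysis stage, and what the synthetic-data generators do and do not
emulate.

## Thermofluor melt-curve model and Tm estimation

A melt curve is modelled as two-state unfolding reported by a hydrophobic
dye:

    F(T) = a + b·T + A / (1 + exp((Tm − T)/s)) + c·max(T − Tm, 0)

with folded-state baseline `a + b·T` (AU, AU/°C), transition amplitude `A`
(AU), midpoint `Tm` (°C), steepness `s` (°C; the transition spans roughly
Tm ± 4s) and post-transition slope `c` (AU/°C, typically negative — dye
dissociates as unfolded protein aggregates).  The generator and the
Boltzmann estimator share this model exactly, so noiseless round-trips are
exact by construction; that is a deliberate design choice, since the
upstream assay literature names the method without giving formulas.

Defaults: `a = 200`, `b = 1.5`, `A = 1000`, `s = 1.5`, `c = −6`, scanned
20–95 °C in 1 °C steps (76 points), matching a real-time PCR thermal ramp.

**Boltzmann method** (primary): non-linear least squares over all six
parameters, initialised from the derivative estimate, with bounds keeping
`A ≥ 0`, `Tm` inside the scanned range and `s ∈ [0.05, 30]`.

**Derivative method**: Savitzky–Golay smoothing (5-point window, quadratic,
the right order for a 1 °C grid where raw differences amplify noise), then
the peak of dF/dT restricted to the rising phase, refined by a 3-point
parabola so midpoints between grid points are resolved.  Before
peak-finding, the pre-transition slope and the unfolded-fraction-weighted
post-transition slope are subtracted; without this correction the decay
term biases the peak low.  A residual bias remains when the decay overlaps
a very broad transition: both methods agree within 0.5 °C for `s ≤ 3` °C on
transitions that complete inside the scanned window, and the bias grows to
~1 °C at `s = 4`.  Transitions that broad (or truncated by the scan end)
should be read from the Boltzmann fit only.

**Transition detection**: no transition is declared when the fitted
amplitude is below 3× the residual RMSE, or the fitted midpoint falls
within 2 °C of either end of the scan.  An all-constant trace short-circuits
to "no transition" rather than an error.

**ΔTm and ranking**: ΔTm is the condition Tm minus the water-control Tm of
the same protein.  Conditions are ranked by the median ΔTm across the
protein panel (pairs with no detected transition are excluded from that
condition's median and counted separately); the stabilisation flag uses a
strict > 4 °C threshold.  Ties in ranking and in per-protein best-condition
selection break on the lexicographically lower condition id, making every
table deterministic.

The default 80-condition storage screen enumerates MES 5.5, Bis-Tris 6.0,
HEPES 7.0/7.5, Tris 7.5/8.0/8.5 and CAPS 9.0, each with no salt or with
NaCl/KCl/MgCl₂ at 50/100/200 mM, buffer-major with the no-salt condition
first.  All components are configurable.

## Malachite-green kinetics

The assay chain is: turnover → PPi → (pyrophosphatase) → 2 Pi → malachite
green A₆₂₃.  Choices:

- **Pi per turnover = 2** by default (configurable to 1 for assays read
  before pyrophosphatase treatment).
- **Standard curve**: ordinary least squares A = slope·c + intercept over a
  13-level 2-fold series from 50 µM down to ≈0.012 µM.
- **Background**: the `background` argument of `absorbance_to_rate` is the
  matrix absorbance *in excess of* the standard-curve blank; the plate
  reducer computes it as mean(substrate-free wells) − intercept.  This
  avoids double-subtracting the reagent blank, which is already in the
  intercept.  Negative net phosphate is floored at zero with a warning.
- **Endpoint-to-rate**: v = Pi / (2·t) assumes the 30-minute endpoint is
  still in the initial-rate regime (substrate consumption small); there is
  no progress-curve fitting.
- **Fit**: unweighted non-linear least squares of v = Vmax·S/(Km+S),
  initialised at Vmax₀ = 1.2·max(v) and Km₀ = the substrate level nearest
  half-maximal rate, positivity enforced through bounds, convergence
  tolerances at 1e−12, standard errors from the Gauss–Newton curvature.
  The default substrate series is 13 2-fold steps from 100 µM (lowest
  ≈0.024 µM), bracketing the half-saturation region for every panel Km.
- **kcat = Vmax / E₀** with a default effective E₀ of 10 in Vmax's
  concentration unit.  This constant is what the published panel's
  Vmax/kcat ratios imply, even though the assay nominally used 0.014 µM
  enzyme; the discrepancy is reported, not resolved, and E₀ is
  configurable.  One panel row (Vmax 0.0102 µM/s) has a ratio of ≈9.3
  rather than 10, so its kcat computes to 0.0010 rather than the tabulated
  0.0011 under the uniform divisor.  Reported kcat values are rounded
  half-up to 4 decimals after snapping to 10 decimals, so a fitted value
  numerically at a .5 boundary rounds the way the printed tables do.
  Vmax is treated as µM·s⁻¹ throughout.

## GC-MS product profiles

- **Background rule**: a sample peak matching a boiled-control peak within
  0.10 min retention time is dropped when its area is ≤ 2× the control area
  and otherwise kept with the control area subtracted.  The factor 2 is a
  conservative invented rule (controls are stated to define "background
  noise" without a criterion); it guarantees retained peaks are at least
  half signal.
- **Classification** is by compound name against a shipped lexicon of ~40
  compounds (class, putative flag, fixed reference retention time).  The
  retention times are synthetic but plausibly ordered for a 60 m
  5 %-phenyl column ramp; only their ordering matters.  Putative
  (library-match-only) compounds are annotated but treated identically in
  arithmetic.
- **Percentages** use only mono- and sesquiterpene peaks in the
  denominator; the internal standard, non-terpene artefacts (geranyl methyl
  ether, pinene hydrate) and unknowns are listed as excluded with reasons.
  The internal standard is used for presence/QC only — percent-of-total
  reporting needs no response-factor correction.  Hedycaryol thermally
  degrades in the inlet and is detected as elemol; the lexicon records the
  alias and `percent_composition(alias_parent=True)` reports the parent
  name.
- **Spectral matching** (`match_spectrum`) is a transparent stand-in for
  proprietary library search: 1000 × squared cosine similarity of
  square-root-scaled intensities, symmetric and scale-invariant.

## Crystallisation-condition mining and screen design

- **Parsing**: conditions split on commas/semicolons; each fragment parses
  as `[number unit] chemical [(pH x)]` with case-insensitive synonym
  normalisation ("PEG 3350" ≡ "PEG-3350" ≡ "polyethylene glycol 3350").
  A bare `%` is read as %w/v (the convention for PEG).  Ammonium sulfate is
  a salt below 0.8 M and a precipitant at ≥ 0.8 M — it legitimately appears
  in both roles in deposited conditions, and concentration is the only
  per-record disambiguator.  Unparseable fragments are retained as
  role=other with a warning; only a fully unparseable non-empty string is
  an error.
- **Frequencies** are per category with category-specific denominators
  (buffers over buffer-reporting records, salts over salt-reporting
  records, etc.; pH binned by integer decade, "6.0–6.9").  A record listing
  two chemicals of one role contributes fractionally so every category sums
  to exactly 100.
- **Selection rule**: top-k buffers by usage (k = 2), a contiguous
  0.5-unit pH ladder of 3·k levels starting at the lower edge of the modal
  pH bin, partitioned in blocks of three among the buffers in frequency
  order — the more-used buffer takes the more acidic block, consistent with
  Bis-Tris buffering below Tris.  Top-2 PEG subtypes (within PEG-containing
  records) and top-2 salts complete the selection.  The pH levels per
  buffer are not derivable from frequencies alone (they were hand-chosen in
  the source screen); this ladder rule is the package's default because it
  reproduces the published six combinations from realistic frequency
  inputs, and the published selection also ships as a fixture
  (`reference_selection()`).
- **Enumeration** is buffer/pH-major, then precipitant in selection order,
  then ascending concentration, 1-based indices; every condition carries
  100 mM buffer and both salts at 200 mM.  The source screen's own ordering
  is unknown, so its best-crystal condition is matched by composition, not
  index.

## Synthetic-data generators

Every generator is a pure function of (parameters, integer seed) using
numpy's PCG64; multi-curve datasets derive per-curve sub-seeds from a
spawned `SeedSequence`, and `regenerate(ground_truth)` reproduces any
dataset bit-identically.  Defaults encode the study conditions: 76-point
melt curves; 13-level 2-fold substrate and standard series; triplicate
wells; multiplicative N(0, cv) plate noise; a 120-entry corpus with 16
unpublished records; salt/precipitant reporting rates of 50/104 and 62/104;
component frequencies matching the mined statistics, with the published
headline percentages kept verbatim and the remaining mass of each category
filled with fixed, plausible named chemicals so categories sum to 100.

What the generators do **not** emulate: raw optics (qPCR fluorescence
gain, CCD shot noise beyond Gaussian), plate spatial effects, substrate
depletion during the endpoint (rates are exact initial rates), GC-MS peak
shape/co-elution/spectra (peak tables are born integrated and assigned),
and real deposition-record messiness beyond case/unit/synonym variation.
Passing tests therefore demonstrate correctness of the analysis logic and
estimator calibration under the stated noise models, not robustness to
every instrument artefact.

## Problem sizes

The test suite and the acceptance script run at the study's own scales —
76-point curves, 13-level series with triplicates, 100-curve and
200-replicate recovery ensembles, 104–200-record corpora — plus one
10,000-record corpus to demonstrate that the component selection stabilises
to the reference outcome at large n.  Everything completes in well under a
minute on one CPU.

## Known limitations

- Single-transition model only: no two-domain melt deconvolution, and the
  upper baseline is a single linear decay.
- No substrate-inhibition or Hill kinetics; no global multi-enzyme fits.
- No raw chromatogram processing (peak picking, deconvolution, retention
  index calibration) and no real spectral library.
- Corpora are ingested from files; there is no live structure-database
  client.
- The derivative Tm estimator is biased for transitions broader than
  s ≈ 3 °C when the post-transition decay overlaps them; use the Boltzmann
  fit there.
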