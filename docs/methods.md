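# Methods

This note documents the models, conventions and numerical choices behind
`phycovoc`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## Measurement model

A culture sample (0.1 l) is dynamically stripped: bubbling transfers
dissolved volatiles into a carrier gas stream that feeds a PTR-TOF mass
spectrometer. Soft chemical ionization by H₃O⁺ protonates each neutral M
to M+H⁺, so a compound of neutral monoisotopic mass m appears at
m/z = m + 1.008. Spectra (30–240 a.m.u.) are acquired every 5 s; the
0.5–5 min window of the stripping run is analyzed.

**Mass calibration.** Reference ions present in every spectrum
(m/z 29.998, 203.943, 330.848) are located as local maxima within
±0.25 Da of their nominal positions, with sub-grid center refinement by
quadratic interpolation of log-intensity (exact for a Gaussian on a
uniform grid). An affine map observed → true is fitted by least squares
and applied to the axis. Affine rather than polynomial: three references
over-determine two coefficients and leave a residual as a quality check
(acceptance tolerance 0.005 Da). References outside the acquisition range
of a given axis are skipped; at least two must be found.

**Binning and peak decomposition.** The calibrated, cycle-summed spectrum
is partitioned into half-open 0.5-Da bins [x−0.25, x+0.25) around
half-integer centers; the upper boundary is excluded by convention, so
m/z 79.25 belongs to bin 79.5. The spectrum-wide baseline (median) is
subtracted and the noise SD estimated as 1.4826 × MAD. A bin is examined
only when its maximum exceeds 3 × noise SD (the detection threshold;
configurable). Within a bin, 1..k Gaussians are fitted (k ≤ 3) by bounded
least squares in local, amplitude-normalized coordinates with an analytic
Jacobian. The number of components is selected automatically — replacing
a manual per-bin examination for reproducibility — by three rules: a
component per prominent local maximum (scipy `find_peaks` with prominence
and 2σ-distance constraints), escalation to an extra component only while
the relative residual drop exceeds 5%, and a stop as soon as residuals
reach the noise floor or a negligible fraction (10⁻⁶) of the bin's
signal, which prevents spurious splitting of clean single peaks. Peak
area is the analytic Gaussian integral amp·σ·√(2π)/Δx (total counts).
Non-convergent fits fall back to a flagged moment estimate. Fits are
performed on the cycle-summed spectrum (rather than per cycle, then
averaged), which is statistically equivalent for a steady signal and far
better conditioned at low signal.

**Feature table.** Fitted peak centers are pooled across samples and
clustered (sorted, split at gaps > 0.02 Da); each cluster becomes an m/z
signal row labeled by its median center at two decimals. A prevalence
filter drops clusters supported by fewer than a minimum number of samples
(default 2; the pipeline uses 3) — one-off noise peaks otherwise inflate
the multiple-testing burden by an order of magnitude. Integrated areas
are normalized to the summed H₃O⁺ primary-ion counts over the same time
window (per-million units, "ncps"). Known contaminants, water clusters
(37.03, 55.04) and fragments are then removed; fragment areas can
optionally be reassigned to their parent.

## Quantification

**Mixing ratios.** The simple-reaction-kinetics estimate converts the
analyte/primary-ion ratio r to a mixing ratio:
ppbv = r / (k·t·N) · 10⁹, with proton-transfer rate coefficient
k = 2×10⁻⁹ cm³ s⁻¹, reaction time t = 10⁻⁴ s and drift-tube gas density
N = 2.46×10¹⁹ cm⁻³ by default. These constants are not compound-specific
here — the method is understood to be accurate to ~30% when the reduced
field exceeds 100 Td (the simulated instrument runs at 126 Td) — and all
are configurable.

**Isotopologue attribution.** For signals with a known formula, the M+1
and M+2 satellites expected from natural isotope abundance
(¹³C 1.07%, ¹⁵N 0.364%, ¹⁸O 0.205%, ³⁴S 4.25%) are matched at
+1.003 / +2.004 Da (±0.01) and folded into the parent when the parent is
sufficiently abundant (default ≥ 0.05 ppbv) and the satellite lies within
a factor [0.5, 2] of its natural-abundance expectation; ambiguous
satellites go to the parent with the closer expectation, and every
attribution is logged. The fractions are first-order
(f_M1 = n_C·a₁₃C + n_N·a₁₅N, f_M2 = n_O·a₁₈O + n_S·a₃₄S); ²H, ¹⁷O, ³³S
and multiple substitutions are outside the considered isotope set. Within
that set the first-order values differ from the exact expansion of the
satellite/parent ratio by at most 1/(1−a₃₄S) ≈ 4.4% for formulas with
≤ 12 carbons. Attribution conserves the table total: values move from
satellite rows to parents, never appear or disappear.

**Stripping equation.** Blank-corrected headspace mixing ratios convert
to the molarity originally dissolved in the stripped liquid as
C_t = (C_c − C_b)·Q·p·t/(V·R·T): a gas stream of Q·t liters at mole
fraction x carries x·Q·p·t/(R·T) moles, collected from volume V. Defaults
follow the experimental setup (Q = 0.3 l h⁻¹, p = 1 atm, t = 4.5 min,
V = 0.1 l, T = 292.15 K — the 19 °C culture temperature). The equation
assumes complete stripping during t; no Henry's-law efficiency factor is
applied. Negative blank-corrected ratios are floored at zero and flagged.
Per-cell pools use fmol cell⁻¹ = (mol l⁻¹ · 10¹⁵)/(cells ml⁻¹ · 10³).

*A note on per-cell units.* Published summaries of experiments of this
kind sometimes pair per-cell and molar figures whose ratio implies
dividing mol l⁻¹ by cells ml⁻¹ without the ml→l factor. `phycovoc` uses
the dimensionally consistent conversion above throughout; the synthetic
generator is anchored on the *concentration* scale (total exponential
pool ≈ 18.5 nM at 2.18×10⁵ cells ml⁻¹), so its per-cell defaults are
smaller by 10³ than figures produced under the inconsistent convention.
All fractions, contrasts and recovery results are unaffected by this
choice.

## Differential analysis

Production: per signal, a two-sided paired t-test of culture vs media
blank across replicate flasks (pairing by replicate index), B-H FDR
across signals within the contrast, then a direction gate — retained iff
mean(culture) > mean(blank), p ≤ 0.05 and Q ≤ 0.1 (both thresholds
configurable; the joint requirement is the default). Depletion: the same
machinery on coculture vs axenic nM tables, restricted to the produced
set of the matching phase, with B-H applied within each coculture × phase
contrast; a constant nonzero paired difference (zero variance) counts as
unbounded evidence rather than a degenerate case, while identical series
give p = 1. Per-cell depletion divides the axenic-minus-coculture mean by
the effective bacterial density — free-living cells (flow cytometry) plus
attached cells (mean attached-per-diatom from electron microscopy of 50
diatoms, times the diatom density). Inflated cocultures can never be
called depleted.

Class aggregation assigns each signal to hydrocarbon / O- / N- /
S-containing / unidentified by elemental makeup with precedence
S > N > O > hydrocarbon for mixed formulas. Profile structure uses
Pearson-correlation-distance average-linkage clustering of treatment
columns, centered PCA, and a one-way PERMANOVA on Euclidean distances
(pseudo-F from the partitioned sums of squared distances; significance by
label permutation with p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), default
9999 permutations in the API, 999 in the bundled pipeline config, always
seeded). The Euclidean metric on cell-normalized profiles is a design
choice; no metric is canonical for these data.

## GCP

Short-term ¹⁴C-bicarbonate uptake approximates gross carbon production:
fixed C (mol) = (DPM_light − DPM_dark)/DPM_added · DIC · V, floored at
zero, with 1 μCi = 2.22×10⁶ DPM for the 2-μCi spike; the rate divides by
incubation time (20 min) and cell count. Stimulation is the percent
increase of a treatment's mean rate over the day-matched axenic control,
tested by a two-sample t-test.

## The synthetic generator

The generator emulates the study conditions: an axenic culture plus five
cocultures, n = 6 replicate flasks, exponential (2.18×10⁵ cells ml⁻¹) and
stationary (10⁶ cells ml⁻¹ default) phases. The compound library fixes
nine anchors (benzene, toluene, ethylbenzene/xylene, C₁₁H₁₆, methanol,
acetaldehyde, acetone, DMS, acetonitrile) and draws the rest from
enumerated C₂–C₁₆ formulas (~15% carry no formula, class "unidentified"),
rejecting masses that would collide with another signal or its satellites
(±0.05 Da), sit within ~3.5σ of a bin boundary, or fall inside a
calibration reference window. Production defaults put the exponential
total at ≈ 18.5 nM with hydrocarbons ≈ 62% of the pool and C₁₁H₁₆
largest; stationary per-cell production is 10% of exponential. Replicate
noise is lognormal with CV 20% (mean-preserving) — a noise law is a
modeling choice; lognormal keeps concentrations positive. Depletion
factors plant coculture-specific regimes (one aggressive consumer, one
depleting only acetaldehyde; methanol and acetone never depleted; ~13/72
signals depleted nowhere).

Spectra are rendered by inverting the quantification chain exactly
(nM → ppbv → counts, split parent/(1+f₁+f₂) and satellites), drawing
Gaussian peaks (σ = 0.02 Da default — plausible for a compact TOF, and
configurable) at affinely drifted positions, adding reference ions,
fixed background/water-cluster peaks at 37.03 and 55.04 (so the exclusion
list has work to do), additive Gaussian noise clipped at zero, and a
constant per-cycle H₃O⁺ signal carried in the series metadata (the
primary ion's own m/z lies below the acquisition window). Because the
forward map is the exact inverse of the processing chain, noise-free
drift-free data must close the loop: recovered concentrations match the
planted ones to well under 1%, and this closure is asserted in the tests.

What the generator does **not** emulate: stripping-efficiency decay over
the run (signals are steady within the analyzed window), compound-
dependent proton-transfer rate coefficients and transmission efficiency,
isotope fine structure beyond single ¹³C/¹⁵N/¹⁸O/³⁴S substitutions,
fragmentation, detector saturation, and bacterial growth dynamics.
Passing recovery tests therefore demonstrates the correctness and
statistical calibration of the analysis chain under the stated noise
model, not robustness to every artifact of real spectra.

## Problem sizes and determinism

The bundled pipeline processes 84 spectrum series (6 treatments × 2
phases × 6 replicates plus blanks) at 0.005 Da axis resolution in about a
minute; tests use reduced designs (12-compound libraries, one phase,
n = 4) and the acceptance script uses 100–500 Monte-Carlo replicates per
check. A single global seed expands into named per-stage substreams
(`numpy.random.SeedSequence`), so any stage can be rerun in isolation and
identical configs yield bit-identical reports (verified by report hash).

## Known limitations

- Two peaks closer than ~2σ (0.04 Da) in one bin are fitted as one; a
  compound coinciding with another's isotopologue satellite is absorbed
  into the attribution.
- The ±30% accuracy of uncalibrated reaction-kinetics quantification is
  inherited, not corrected; only relative contrasts are calibration-free.
- The PERMANOVA permutes labels freely (one-way design); no strata for
  replicate pairing.
- B-H is applied within each contrast, not globally across cocultures,
  matching per-contrast reporting of significant-signal counts.
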