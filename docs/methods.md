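# Methods

This note documents the models, conventions and tunable parameters behind the
`marado` identification cascade, the assumptions baked into the synthetic-data
generator, and the places where the design was genuinely open.

## Chemistry and mass conventions

A maradolipid is assembled as trehalose (C₁₂H₂₂O₁₁) plus one free fatty acid
per acyl position minus one water per ester bond; an acyl chain *n*:*d* has
the free-acid formula CₙH₂ₙ₋₂dO₂. The 6 and 6′ positions of trehalose are
chemically equivalent, so acyl pairs are stored in canonical ascending
(carbons, double-bond equivalents) order and `Mar(a/b)` ≡ `Mar(b/a)`.
Branched and cyclopropane-ring chains are formula-identical to their
straight/unsaturated counterparts (a ring counts as one DBE); the flags are
carried as information only. Distinct compositions with identical formulas —
the isobars Mar(16:0/16:0) and Mar(15:0/17:0), both C₄₄H₈₂O₁₃ — remain
distinct objects throughout.

Monoisotopic masses use CODATA/IUPAC atomic masses (C = 12 exactly,
H = 1.00782503207, N = 14.0030740048, O = 15.9949146196, Na = 22.9897692809 Da).
All ions are singly charged, and the electron mass (0.00054858 Da) is included
in every ion m/z; "FA" in [M+FA−H]⁻ is formate from the formic-acid mobile
phase, with an attachment shift of +44.998203 Da. Computed adduct m/z agree
with the packaged standards table to better than 0.0005 Da (the table's
printed precision).

The negative-mode fragment catalogue follows the observed cascade: formate
adduct → [M−H]⁻ → acyl loss as neutral ([M−RCOOH]⁻) or carboxylate
([RCOO]⁻) → dehydrated trehalose head fragments at m/z 323.0984 and
305.0878. Symmetric diacyl species emit a single neutral-loss fragment. For
lyso species the acyl neutral loss *is* the 323.0984 head fragment (emitted
once), and the doubly dehydrated fragment is not produced — which is exactly
what makes the 323/305 co-elution screen class-diagnostic. Published screen
extractions sometimes quote slightly different values (323.0972/305.0877);
the theoretical values are treated as canonical here and the 0.05 Da EIC
window covers both.

## Kendrick chain

Nominal Kendrick mass uses the **floor** convention: only KMD = KM − ⌊KM⌋
reproduces the reference anchor 0.6094 from the Mar(32:0) formate adduct m/z
863.5737 (rounding would give −0.39). The anchor is computed from the adduct
m/z, not the neutral mass, again fixed by the printed value. The RKMD divisor
0.013399 is the Kendrick mass defect of H₂ evaluated from first principles
(2 × 1.00782503207 × 14/14.015650 − 2 = 0.0133994). Allowed RKMD integers
default to {0, −1, −2, −3, −4} (double bonds only lower the defect); the
tolerance is ±0.1. Both are configurable because the exact integer set used
in practice is data-dependent.

Lysomaradolipids carry one oxygen fewer per CH₂-ladder than diacyl species,
so the diacyl anchor cannot retain them (their RKMD sits ≈ +2.7 off the
grid). The lyso cascade therefore uses its own anchor, the KMD of the
LysoMar(17:0) formate adduct — every saturated lyso homolog shares this value
exactly, and unsaturated members fall on the same −d ladder.

## CCS calibration

Mason–Schamp with Ω = (3ze/16N₀)·√(2π/(μ k_B T))·(1/K₀), with
N₀ = 2.6867811 × 10²⁵ m⁻³ (Loschmidt), e = 1.602176634 × 10⁻¹⁹ C,
k_B = 1.380649 × 10⁻²³ J/K, N₂ gas mass 28.006148 Da, and μ the ion–gas
reduced mass. Stepped-field fits regress arrival time on 1/V
(t_d = L²/(KV) + t_fix, default tube length 0.7803 m), normalize K to K₀ at
273.15 K/760 Torr, and report R². Single-field calibration fits
t_A = β·(√μ/|z|)·Ω + t_fix on ≥2 reference ions (the packaged tune-mix ions:
m/z 922.009799 at 243.64 Å² positive, 1033.987012 at 255.34 Å² negative).
Forward and inverse conversions are algebraically exact inverses (tested to
1 × 10⁻⁹ relative).

The drift-tube temperature is not an observable of this package; it defaults
to 305 K and cancels in every calibration roundtrip, so it only matters if
absolute K₀ values are compared across packages. Pressure defaults to
3.95 Torr. The percent deviation between single- and stepped-field CCS is
reported as 100 × (single − stepped)/stepped, the convention consistent with
the packaged negative-mode reference rows; the deviation values that
circulate for the positive-mode rows are sign-inconsistent with that
convention and are not used as an anchor.

## DIA fragment assignment

EIC windows are read as *total* widths: 0.05 Da in m/z (±0.025) and 2 ms in
drift time (±1 ms). Smoothing is a centered moving average — 3 points along
RT, 5 along drift, matching common preprocessor settings — with shrunken
windows at grid edges so interior peak areas are preserved to ≲0.1 %.
Correlation is computed on smoothed traces (the choice raw-vs-smoothed is
open in practice; smoothed is the default here and configurable) over the
precursor apex ± 3σ, σ estimated from the FWHM of the precursor peak, with a
minimum of 5 overlapping grid points; zero-variance or too-short overlaps are
conservatively "not retained". The retention threshold is the strict
inequality r > 0.9.

The diagnostic screen extracts the two head-fragment EICs over the whole run
without drift filtering; apexes of the 323 trace with a 305 partner within
2 RT steps (≥ grid resolution) are diacyl hints, unpartnered 323 apexes are
lyso hints.

## Candidate library and matching

The default fatty-acid pool is C13–C20 × 0–2 DBE with the C15:0/C17:0 entries
flagged branched (iso-methyl), approximating the composition reported for
dauer glycolipids; it is fully configurable and deduplicated on
(carbons, DBE) since formula-identical chains generate identical candidate
masses. Diacyl candidates enumerate unordered pairs with repetition
(k(k+1)/2 for k chains), lyso candidates the k single chains. MS1 matching
uses ±5 mDa and class RT windows 12–17 min (diacyl) / 2.5–6.5 min (lyso);
ambiguity over isobaric candidates is preserved and resolved later by acyl
fragments or standards. Replicate alignment is greedy centroid clustering in
descending-abundance order with the vendor-style composite tolerances
(±10 % + 0.5 min RT, ±1.5 % drift, ±15 ppm + 2 mDa mass) — deterministic by
construction.

## Trendlines and MSI levels

Trendlines are fitted per series (class, double-bond count, adduct) with the
total acyl carbon number as predictor, so formula-isomers share an
x-coordinate. CCS is always linear; RT is quadratic when ≥4 distinct chain
lengths are available, else linear. Validation tolerances default to 2 %
(RT) and 0.4 % (CCS), the observed error bounds of standard-matched species.

MSI level 1 requires an authentic-standard match on all of m/z (±5 mDa), RT
(±2 %) and CCS (±0.4 %), ties broken by combined normalized distance — this
is what separates the isobar pair by RT. Level 2 requires the diagnostic
head fragments plus a candidate-specific acyl fragment, or trendline support;
whether fragment evidence is mandatory is configurable because low-intensity
precursors may legitimately lack it. Level 3 is m/z-only. In the lyso
cascade, features whose spectra show *both* head fragments are demoted
(diacyl signature) and excluded.

## Synthetic data generator

The generator emulates the acquisition geometry the analysis assumes, not the
instrument physics: each species is a 2D Gaussian in (RT, drift), centered at
its RT and the arrival time implied by its CCS through the same single-field
calibration the analyzer uses (roundtrip exact to 1 × 10⁻⁶); fragments share
the precursor's RT profile and drift position (drift separation precedes
fragmentation) and appear in the high-energy frames with energy-dependent
fractions — neutral losses only at 20 eV, carboxylate and head fragments
maximal at 40 eV, mostly intact precursor plus a weak 323 fragment at 10 eV.
Defaults: RT grid 0.03 min with σ 0.05 min, drift grid 0.1 ms with σ 0.2 ms,
18-min run, 1 % multiplicative log-normal intensity noise plus a ≤1-count
uniform floor, calibration β = 0.02, t_fix = 0.5 ms. Points below 0.5 counts
are dropped to keep tables compact.

It does **not** simulate chromatographic tailing, isotope envelopes, detector
saturation, centroiding error or multiply charged species. Passing tests on
this generator therefore demonstrate the correctness of the filtering and
evidence logic under the stated statistical structure, not robustness to
every artifact of real instrument data.

Decoys probe each gate separately: features off the RKMD grid (rejection by
the Kendrick filter), head-fragment lookalikes at shifted RT (rejection by
the correlation gate), and co-drifting ions 0.2 Da outside the m/z window
(exclusion by EIC extraction). The packaged benchmark — ten standards planted
at their reference RT/CCS plus 50 decoy features, ten seeds — runs in well
under a minute and achieves 100 % recall at MSI ≤ 2 with ≥95 % decoy
rejection; chimeric distortion of shared-m/z fragment EICs by closely
co-eluting species is reproduced by the generator and is the reason fragment
evidence occasionally fails for individual species, in which case trendline
or standard evidence carries the annotation, as it would in practice.

## Known limitations

* Vendor raw files and 4D peak picking are out of scope; frame data enters as
  a documented long table (rt_min, dt_ms, mz, intensity, energy, ce_ev).
* The RKMD integer set, lyso Kendrick anchor and fatty-acid pool are
  field-realistic defaults, not measured properties of any specific sample.
* Trendline validation needs ≥2 distinct chain lengths per series; series
  with a single standard return "no model" rather than a verdict.
* Positive-mode coverage stops at the expected fragment list ([M−H₂O+H]⁺,
  acylium ions); the identification cascade itself runs on negative-mode data.
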