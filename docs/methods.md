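# Methods

This note documents the models, defaults and design choices behind
`lipidccs`: what each stage computes, why the defaults are what they are,
and what the synthetic data does and does not emulate.

## Lipid model

Lipids are handled at species level: class + total acyl carbons : total
double bonds (e.g. `PC 34:2`), with an optional elution-order index for
chromatographically resolved isomers (`TG 48:2 (2)`). sn-positions and
individual acyl chains are out of scope — the reference library resolves
lipids only to species level. The ¹³C-labeling status is a separate flag
(CSV column `label`, values `U13C`/`12C`), never part of the name, because
the same species identity exists in both forms and must match across them.

Five singly charged adducts are supported, with fixed charge-carrier mass
deltas (Da): [M+H]⁺ +1.007276, [M+NH₄]⁺ +18.033823, [M+Na]⁺ +22.989218,
[M−H]⁻ −1.007276, [M+HCOO]⁻ +44.998201. Uniform ¹³C labeling shifts the
neutral mass by n_C × 1.0033548 Da.

`isotopologue_apparent_shift` computes √(μ_heavy/μ_light) − 1 with
μ = m·M_gas/(m + M_gas): the apparent CCS offset between isotopologues of
identical structure when mobilities are converted to CCS without accounting
for the ion-mass change. It is a diagnostic for the small (~0.1–0.3%)
labeled-vs-unlabeled shift visible at moderate IM resolution, not a
correction, and no exact magnitude is asserted for it.

## Library curation

Observations are grouped by (species, adduct) across a dilution series and
filtered in a fixed order so every rejection has exactly one primary reason:

1. **Mass accuracy** — every observation within |ppm| ≤ 5 (inclusive, on the
   absolute error).
2. **Minimum detections** — at least 2 distinct dilutions.
3. **Coelution of adducts** — the group's mean RT must lie within 0.1 min
   (default, configurable) of the species-level *median* RT over all the
   species' adduct groups, both polarities pooled. The median makes the
   criterion robust when three or more adducts are present; with exactly two
   adducts an RT discrepancy rejects both, which is the conservative choice
   when there is no way to tell which adduct is the mis-assignment.
4. **CCS repeatability** — sample RSD (sd/mean × 100) < 1% (exclusive).

Retained groups become entries with the arithmetic-mean CCS as the
reference value and `n_detections` = number of distinct dilutions. The
thresholds for (1), (2) and (4) are the published criteria; the 0.1 min
coelution tolerance is this package's default because no numeric tolerance
is published — it is tight relative to typical RP-LC peak widths while
allowing small inter-run drift.

ECN validation scans all entry pairs of a class–adduct combination and
reports pairs violating either monotonicity direction (same double bonds,
more carbons, CCS not larger; same carbons, more double bonds, CCS not
smaller). Isomer pairs (identical C:DB) are not compared.

## Bias monitoring

Matching is by canonical name + adduct (a targeted workflow; no m/z or RT
tolerance search). Only labeled measured ions are matched — the library
contains labeled lipids — while unlabeled ions are carried through to the
correction stage. A measured ion lacking an isomer index that maps to more
than one library isomer is excluded and reported as ambiguous rather than
guessed by RT. Summaries (n, mean signed bias, mean absolute bias, min,
max) are produced per (class, adduct, polarity) and rolled up per
ionization mode, each matched ion weighted equally. Both per-file and
across-file-mean granularities are supported; the mean mode mirrors
correcting the average of a measurement sequence.

## Correction ensembles

For each class–adduct combination with ≥ 3 matched labeled standards,
subsets of 3–6 standards are enumerated. If the number of such subsets is at
most the cap (default 100) all are used; otherwise exactly `cap` subsets are
drawn uniformly without replacement over all sizes pooled, using a seeded
generator and combinatorial unranking (no materialization of the full subset
space). The ensemble size is therefore min(cap, Σₖ C(n,k), k = 3..min(6,n)).
Pooled-uniform sampling (rather than per-size quotas) was chosen because it
is the distribution-free reading of "up to 100 distinct functions using 3–6
lipids"; the seed is recorded in every output header.

Each subset yields an OLS fit of reference CCS (response) on measured CCS
(predictor), so a corrected value is obtained by plugging the measured CCS
straight into the function. Degenerate subsets (constant predictor) raise an
error. The quality rule — slope within [0.8, 1.2] and r² ≥ 0.99, both
configurable — flags functions that cannot represent a plausible
instrument-calibration bias (observed real biases are ~±1%, i.e. slopes very
near 1; the rule comfortably rejects pathological slopes like 0.01, 0.46 or
2.42 while tolerating noise on small subsets). Flagged functions remain in
all reports but are excluded from the per-lipid point estimate, defined as
the median of the corrected values across non-flagged functions (median
because the ensemble distribution is the primary output and the median is
robust to a residual poor fit). If every function of a group is flagged, the
one with slope closest to 1 is retained so the group still yields estimates,
with the retention noted in its flag reason.

Before/after bias distributions are computed on the labeled standards;
corrections are applied to every lipid of the combination irrespective of
labeling.

## Synthetic data

The generator emulates: per-class ECN structure of true CCS values (base +
per-carbon increment − per-double-bond decrement, both strictly positive by
construction, so the truth is always ECN-consistent); an affine
inter-platform bias parameterized in the correction orientation
(CCS_true = slope·CCS_biased + intercept, so a noise-free fit recovers the
injected pair exactly); multiplicative Gaussian CCS noise (sd as percent of
the true CCS, matching the percent-RSD quality criterion); replicate
observations across dilutions; and optional planted violations of each
curation filter, with the expected rejections recorded in the emitted truth.

Defaults are the study conditions: the 10 correctable classes (Cer, DG,
HexCer, LPC, PA, PC, PE, PI, PS, TG) with typical adducts, 8 labeled lipids
per class–adduct combination, correction-truth slope 0.988 and intercept
0.5 Å² (≈ +1% measured bias, within the reported −0.31…1.08% per-class
range, and positive like most real cross-platform biases), 0.2% noise, 3
dilutions and 3 files. Unlabeled twins of every species are emitted so the
apply-to-all-lipids path is exercised.

Not emulated: raw mobilograms and peak shapes, isotope envelopes, the
reduced-mass isotopologue CCS shift (labeled and unlabeled twins share the
same true CCS), RT drift between runs, class-correlated noise, and missing
ions. Passing tests on this generator therefore demonstrate the statistical
machinery (matching, filtering, fitting, flagging, bias accounting) under
controlled truth, not robustness to every artifact of real exports.

## Packaged reference library

The real drift-tube reference table cannot be redistributed, so the package
ships a deterministic synthetic stand-in (`lipidccs.reference`, file
`data/u13c_yeast_dtccs_library.synthetic.csv`) that reproduces the published
aggregate composition exactly: 377 entries, 162 labeled species, 15 classes,
5 adducts, m/z 318.3501–966.9794, CCS 189.4–327.1 Å², ECN-consistent within
every class–adduct combination, and with exactly the 10 correctable classes
carrying ≥ 3 lipids in at least one adduct. Masses come from an additive
monoisotopic model anchored on real species — notably, the m/z endpoints are
the real U¹³C forms of SPH 18:1 [M+H]⁺ (318.3501) and TG 54:2 [M+Na]⁺
(966.9794). CCS values come from per-class affine ECN models near published
drift-tube values, with the endpoints pinned to the published range. The
per-entry CCS values are synthetic: analyses that depend on individual
reference values (rather than composition, coverage and trends) require a
user-supplied curated library.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on the [x, 1] design; r² floor/ceiling to
  [0, 1] against floating-point drift on perfect fits.
* dtccs aggregation = arithmetic mean; RSD = sample sd / mean × 100
  (ddof = 1); a single observation has RSD 0 but is rejected earlier by the
  minimum-detections filter when dilutions are missing.
* ppm filter inclusive (≤ 5), RSD filter exclusive (< 1%), matching the
  stated wording of the criteria.
* Subset order is (size, lexicographic rank); sampling uses
  `numpy.random.default_rng(seed)`; all outputs are bit-reproducible for a
  fixed seed.
* CSV outputs round m/z to 4 decimals, RT to 3, CCS to 4 (library reference
  values to 1 in the packaged table, the printed precision of drift-tube
  libraries).

## Problem sizes

The test suite and the acceptance script use simulations sized for quick,
deterministic runs: 8 standards per group (the default study condition),
100 replicates for the stochastic-recovery study, 1000 random instances for
the OLS oracle comparison, and single-class configurations where only the
regression behaviour is under study. These sizes give standard errors far
below the asserted tolerances.

## Known limitations

* Matching is strictly name-based; no fuzzy or m/z-window identification.
* Corrections are per class–adduct and affine only; no cross-class pooling,
  no m/z- or mobility-dependent terms, and no special handling for TWIM
  calibration characteristics.
* The mode-level bias recomputation of the original measured exports can
  only run when a user supplies those tables (see
  `tests/test_acceptance.py`); they are third-party data not shipped here.
* Errors-in-variables attenuation: the regression predictor (measured CCS)
  is itself noisy, so fitted slopes are attenuated by a factor of about
  1 − σ²_noise/σ²_spread. At 0.2% noise and typical within-group CCS spreads
  (> 10 Å²) this is well under 1% of the slope and does not bias corrected
  values, which remain calibrated predictions.
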