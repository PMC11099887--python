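# lipidccs

Internal CCS quality control for ion mobility–mass spectrometry (IM-MS)
lipidomics using uniformly ¹³C-labeled lipids as internal standards.

## The problem

IM-MS adds a collision cross section (CCS, in Å²) to every lipid ion — a
conditional physicochemical descriptor that supports lipid annotation.
Drift-tube instruments (DTIM) measure CCS nearly from first principles, but
trapped-ion (TIM) and traveling-wave (TWIM) instruments rely on external CCS
calibration with calibrants that are chemically unlike lipids, which leaves a
small systematic bias (typically well under 2%) in the reported CCS values.

`lipidccs` addresses this with *internal* standardization: a fully
¹³C-labeled yeast lipid extract is spiked into the sample, its lipids are
measured alongside the analytes, and their CCS values are compared with a
curated drift-tube reference library (ᴰᵀCCS_N₂) of the same labeled species.
The signed percent bias

    bias% = (CCS_measured − CCS_reference) / CCS_reference × 100

is monitored per lipid class, adduct and ionization mode, and — where at
least three labeled standards of a lipid class–adduct combination are
present — corrected with an ensemble of up to 100 linear functions

    CCS_corrected = a · CCS_measured + b

each fitted by ordinary least squares on a distinct subset of 3–6 labeled
standards (reference regressed on measured, so the measured value is plugged
in directly). Every lipid of the combination is corrected regardless of its
labeling status; functions with an implausible slope (outside [0.8, 1.2]) or
a poor fit (r² < 0.99) are flagged and excluded from the per-lipid point
estimate (the median over the remaining functions).

The package also contains:

* **Library curation** from replicate dilution-series observations with four
  criteria applied in order: mass accuracy ≤ 5 ppm, detection in ≥ 2
  dilutions, coelution of adducts (RT within 0.1 min of the species median),
  CCS RSD < 1% — plus validation of the equivalent-carbon-number (ECN) trend
  transferred to the CCS dimension (longer chains ⇒ larger CCS, more double
  bonds ⇒ smaller CCS).
* **A packaged synthetic reference library** with the published composition
  (377 entries, 162 labeled species, 15 lipid classes, 5 adduct types, m/z
  318.3501–966.9794, CCS 189.4–327.1 Å²); see
  `lipidccs.reference` for how it is constructed and what it stands in for.
* **A synthetic-data generator** (`lipidccs.simulate`) producing libraries,
  observation tables and biased measured tables with known ground truth.

## Worked example

```bash
python examples/03_ccs_correction.py
```

simulates a measured dataset with a known ~+1% affine bias and 0.2% noise,
fits the correction ensembles and prints (abridged):

```
  class adduct     n_std n_fns flagged  before%   after%
    Cer [M+H]+         8   100       0   +1.031  -0.0037
     DG [M+NH4]+       8   100       1   +1.110  -0.0033
     PC [M+H]+         8   100      31   +0.909  -0.0164
     TG [M+NH4]+       8   100      22   +1.059  -0.0043

corrected 240 lipid ions in 15 class-adduct groups
```

Each row is one lipid class–adduct combination: `n_std` labeled internal
standards were matched to the reference library, `n_fns` correction functions
were fitted (100 = the subset cap), `flagged` of them were rejected by the
quality rule, and the mean signed group bias drops from about +1% before
correction to approximately 0% after. The other examples cover library
inspection (`01`), bias monitoring (`02`) and curation with planted
violations (`04`).

The same workflow is available as a CLI:

```bash
lipidccs simulate --out sim --seed 1
lipidccs curate   --observations sim/observations.csv --out curated
lipidccs monitor  --measured sim/measured.csv --library sim/library.csv --out qc
lipidccs correct  --measured sim/measured.csv --library sim/library.csv --out corrected
```

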