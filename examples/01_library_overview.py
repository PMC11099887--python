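"""Inspect the packaged U13C reference CCS library.

Loads the synthetic reference library (DTCCS_N2 values for uniformly
13C-labeled yeast lipids), prints its composition, and verifies that every
lipid class-adduct combination follows the ECN trend transferred to the CCS
dimension (longer acyl chains -> larger CCS, more double bonds -> smaller).
"""

from lipidccs import library_summary, load_reference_library
from lipidccs.library import ecn_trend_validate_all

library = load_reference_library()
s = library_summary(library)

print(f"entries:          {s['n_entries']}")
print(f"lipid species:    {s['n_species']}")
print(f"lipid classes:    {s['n_classes']}  ({', '.join(library.classes())})")
print(f"adduct types:     {s['n_adducts']}")
print(f"m/z range:        {s['mz_min']:.4f} - {s['mz_max']:.4f}")
print(f"CCS range (A^2):  {s['dtccs_min']:.1f} - {s['dtccs_max']:.1f}")

violations = ecn_trend_validate_all(library)
print(f"ECN violations:   {sum(len(v) for v in violations.values())}")
print()
print("Each entry is one (species, adduct) reference value; zero ECN")
print("violations means chain length/unsaturation order CCS consistently.")
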