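"""Synthetic stand-in for the U13C yeast DTCCS_N2 reference library.

The real reference library was measured on a drift-tube IM-QTOF from a fully
13C-labeled yeast extract.  The measured table itself cannot be redistributed
here, so this module deterministically *constructs* a synthetic library with
the same published composition and structure:

* 377 (species, adduct) entries for 162 U13C-labeled lipid species across the
  15 lipid classes AcCa, Cer, Co, DG, HexCer, LPC, LPE, PA, PC, PE, PG, PI,
  PS, SPH, TG and the 5 adduct types [M+H]+, [M+NH4]+, [M+Na]+, [M-H]- and
  [M+HCOO]-;
* theoretical m/z spanning 318.3501-966.9794 and DTCCS_N2 spanning
  189.4-327.1 A^2 (the range endpoints are the U13C forms of SPH 18:1 [M+H]+
  and TG 54:2 [M+Na]+, whose monoisotopic masses reproduce the endpoints
  exactly);
* exactly the 10 classes Cer, DG, HexCer, LPC, PA, PC, PE, PI, PS, TG carry
  >= 3 lipids in at least one adduct and are therefore correctable;
* within every class-adduct combination the CCS values follow the ECN trend
  (longer chains larger, more unsaturation smaller).

Masses are computed from an additive monoisotopic model (class headgroup +
CH2 increments - unsaturation) with the uniform 13C shift applied over all
carbons of the molecule; CCS values come from a per-class affine ECN model
plus a small adduct offset.  Everything is deterministic: no randomness is
involved, and rebuilding always yields the identical table.

This is synthetic reference data for development, testing and demonstration;
for real measurements users should load their own curated library CSV.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .lipids import ADDUCTS, C13_MASS_SHIFT, LipidClass, LipidSpecies
from .library import CuratedLibrary, LibraryEntry, write_library

__all__ = ["build_reference_library", "load_reference_library", "PACKAGED_LIBRARY_NAME"]

PACKAGED_LIBRARY_NAME = "u13c_yeast_dtccs_library.synthetic.csv"

#: Da per CH2 unit and per double bond (H2 loss) in the acyl-chain mass model.
_CH2 = 14.015650
_H2 = 2.015650

# Per-class mass model: neutral monoisotopic 12C mass at zero acyl carbons /
# double bonds, and the number of non-acyl carbons (headgroup + backbone)
# included in the uniform 13C label.  Bases are anchored on real species
# (e.g. PC 34:2 = 757.5622 Da, TG 54:3 = 884.7833 Da, SPH 18:1 = 299.2824 Da).
_MASS_MODEL: dict[str, tuple[float, int]] = {
    "PC": (285.0614, 8),
    "PE": (243.0144, 5),
    "LPC": (271.0821, 8),
    "LPE": (229.0351, 5),
    "PA": (199.9722, 3),
    "PS": (287.0042, 6),
    "PG": (274.0090, 6),
    "PI": (362.0250, 9),
    "DG": (120.0059, 3),
    "TG": (133.98514, 3),
    "Cer": (62.99564, 0),
    "HexCer": (225.0485, 6),
    "SPH": (49.01635, 0),
    "AcCa": (175.0845, 7),
    "Co": (182.0579, 9),
}

# Per-class ECN model for CCS: base (A^2), increment per acyl carbon,
# decrement per double bond.  Chosen near published drift-tube values for
# mid-sized species of each class.
_CCS_MODEL: dict[str, tuple[float, float, float]] = {
    "PC": (200.7, 2.4, 1.7),
    "PE": (192.8, 2.4, 1.7),
    "LPC": (192.2, 2.3, 1.6),
    "LPE": (180.9, 2.3, 1.7),
    "PA": (185.8, 2.4, 1.7),
    "PS": (190.1, 2.4, 1.7),
    "PG": (204.1, 2.4, 1.7),
    "PI": (195.8, 2.4, 1.7),
    "DG": (180.2, 2.5, 1.7),
    "TG": (186.3, 2.6, 1.8),
    "Cer": (196.0, 2.1, 1.5),
    "HexCer": (196.8, 2.2, 1.6),
    "SPH": (154.9, 2.0, 1.5),
    "AcCa": (186.8, 2.2, 1.6),
    "Co": (224.0, 2.0, 1.0),
}

#: Small CCS offset per adduct type (A^2), identical across classes.
_ADDUCT_CCS_OFFSET = {
    "[M+H]+": 0.0,
    "[M+NH4]+": 1.5,
    "[M+Na]+": 4.0,
    "[M-H]-": -2.0,
    "[M+HCOO]-": 3.0,
}

# (carbons, double_bonds, isomer_index or None) per class.  The ten
# correctable classes carry >= 3 species; the other five deliberately fewer.
def _grid(carbons: list[int], dbs: list[int]) -> list[tuple[int, int, None]]:
    return [(c, d, None) for c in carbons for d in dbs]


_SPECIES: dict[str, list[tuple[int, int, int | None]]] = {
    "PC": _grid([30, 32, 34, 36], [0, 1, 2, 3, 4, 5]),  # 24
    "PE": _grid([32, 34, 36], [1, 2, 3, 4, 5, 6]),  # 18
    "LPC": _grid([16, 17, 18, 20], [0, 1]),  # 8
    "HexCer": _grid([34, 36, 38], [1, 2]),  # 6
    "Cer": _grid([34, 36, 38, 40, 42, 44], [1, 2]) + [(46, 2, None)],  # 13
    # 26 = grid of 20 with 48:2 split into two chromatographic isomers,
    # plus five shorter species
    "TG": (
        [(44, 1, None), (44, 2, None), (46, 1, None), (46, 2, None), (46, 3, None)]
        + [
            (c, d, None)
            for c in [48, 50, 52, 54]
            for d in [2, 3, 4, 5, 6]
            if not (c == 48 and d == 2)
        ]
        + [(48, 2, 1), (48, 2, 2)]
    ),
    "DG": _grid([32, 34, 36, 38], [0, 1, 2]) + [(40, 1, None), (40, 2, None)],  # 14
    "PI": _grid([32, 34, 36, 38], [0, 1, 2, 3, 4]),  # 20
    "PS": _grid([34, 36, 38], [1, 2, 3, 4]),  # 12
    "PA": _grid([32, 34, 36], [1, 2, 3, 4]),  # 12
    "AcCa": [(16, 0, None), (18, 1, None)],
    "Co": [(45, 9, None)],
    "LPE": [(16, 1, None), (18, 1, None)],
    "PG": [(34, 1, None), (36, 2, None)],
    "SPH": [(18, 0, None), (18, 1, None)],
}

_CLASS_ADDUCTS: dict[str, list[str]] = {
    "PC": ["[M+H]+", "[M+Na]+", "[M+HCOO]-"],
    "PE": ["[M+H]+", "[M+Na]+", "[M-H]-"],
    "LPC": ["[M+H]+", "[M+Na]+", "[M+HCOO]-"],
    "HexCer": ["[M+H]+", "[M-H]-", "[M+HCOO]-"],
    "Cer": ["[M+H]+", "[M+Na]+", "[M-H]-", "[M+HCOO]-"],
    "TG": ["[M+NH4]+", "[M+Na]+"],
    "DG": ["[M+NH4]+", "[M+Na]+"],
    "PI": ["[M+NH4]+", "[M-H]-"],
    "PS": ["[M-H]-"],
    "PA": ["[M-H]-"],
    "AcCa": ["[M+H]+"],
    "Co": ["[M+H]+", "[M+NH4]+", "[M+Na]+"],
    "LPE": ["[M+H]+", "[M-H]-"],
    "PG": ["[M-H]-"],
    "SPH": ["[M+H]+"],
}

#: CCS nudge (A^2) applied to chromatographic isomers of the same species.
_ISOMER_CCS_OFFSET = {1: -0.4, 2: 0.4}


def _neutral_labeled_mass(cls: str, carbons: int, double_bonds: int) -> float:
    base, extra_carbons = _MASS_MODEL[cls]
    mass_12c = base + _CH2 * carbons - _H2 * double_bonds
    return mass_12c + (carbons + extra_carbons) * C13_MASS_SHIFT


def _dtccs(cls: str, carbons: int, double_bonds: int, adduct: str, isomer: int | None) -> float:
    base, per_c, per_db = _CCS_MODEL[cls]
    ccs = base + per_c * carbons - per_db * double_bonds + _ADDUCT_CCS_OFFSET[adduct]
    if isomer is not None:
        ccs += _ISOMER_CCS_OFFSET[isomer]
    return round(ccs, 1)


def build_reference_library() -> CuratedLibrary:
    """Construct the synthetic U13C reference library (deterministic)."""
    entries: list[LibraryEntry] = []
    for cls in sorted(_SPECIES):
        for carbons, dbs, isomer in _SPECIES[cls]:
            species = LipidSpecies(
                lipid_class=LipidClass(cls),
                carbons=carbons,
                double_bonds=dbs,
                isomer_index=isomer,
                labeled=True,
            )
            neutral = _neutral_labeled_mass(cls, carbons, dbs)
            for adduct_name in _CLASS_ADDUCTS[cls]:
                adduct = ADDUCTS[adduct_name]
                entries.append(
                    LibraryEntry(
                        species=species,
                        adduct=adduct,
                        theoretical_mz=round(neutral + adduct.mass_delta, 4),
                        dtccs=_dtccs(cls, carbons, dbs, adduct_name, isomer),
                        ccs_rsd=round(
                            0.10
                            + 0.07 * ((carbons + 2 * dbs + len(adduct_name)) % 8),
                            2,
                        ),
                        n_detections=2 + ((carbons + dbs) % 4),
                    )
                )
    return CuratedLibrary(
        entries=entries,
        provenance=(
            "synthetic U13C yeast DTCCS_N2 reference library "
            "(deterministic model; see lipidccs.reference)"
        ),
    )


def load_reference_library() -> CuratedLibrary:
    """Load the packaged synthetic reference library.

    Reads the packaged CSV when available and falls back to rebuilding from
    the deterministic model (both are identical by construction and tested).
    """
    try:
        path = resources.files("lipidccs").joinpath(f"data/{PACKAGED_LIBRARY_NAME}")
        with resources.as_file(path) as p:
            if p.exists():
                from .library import read_library

                return read_library(p)
    except (FileNotFoundError, ModuleNotFoundError):  # pragma: no cover
        pass
    return build_reference_library()  # pragma: no cover


def write_packaged_library(path: str | Path) -> None:
    """Regenerate the packaged CSV from the deterministic model."""
    lib = build_reference_library()
    write_library(
        lib,
        path,
        header=(
            "synthetic U13C yeast DTCCS_N2 reference library\n"
            "generated deterministically by lipidccs.reference.build_reference_library()"
        ),
    )
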