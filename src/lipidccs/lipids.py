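"""Species-level lipid nomenclature, adducts and small mass utilities.

Lipids are handled at *species level*: a lipid class plus the total number of
fatty acyl carbons and double bonds, e.g. ``PC 34:2``.  Chromatographically
resolved isomers of the same species are distinguished by a trailing elution
order index in parentheses, e.g. ``TG 48:2 (2)``.  Whether a species is the
uniformly 13C-labeled internal-standard form or the unlabeled analyte form is
carried as a separate flag / CSV column (values ``U13C`` and ``12C``), never
encoded in the name, because the same species identity exists in both forms
and must match across them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "LipidClass",
    "LipidSpecies",
    "Adduct",
    "ADDUCTS",
    "LipidNameError",
    "parse_lipid_name",
    "adduct_mz",
    "u13c_mass_shift",
    "ppm_error",
    "isotopologue_apparent_shift",
    "PROTON_MASS",
    "C13_MASS_SHIFT",
    "N2_MASS",
]

#: Mass of a proton in Da (charge carrier for [M+H]+ / [M-H]-).
PROTON_MASS = 1.007276

#: Monoisotopic mass difference 13C - 12C in Da.
C13_MASS_SHIFT = 13.0033548 - 12.0


#: Monoisotopic mass of the N2 buffer gas in Da.
N2_MASS = 28.0134


class LipidClass(str, Enum):
    """The 15 lipid classes covered by the U13C yeast reference library."""

    AcCa = "AcCa"  # acylcarnitine
    Cer = "Cer"  # ceramide
    Co = "Co"  # coenzyme
    DG = "DG"  # diacylglycerol
    HexCer = "HexCer"  # hexosylceramide
    LPC = "LPC"  # lysophosphatidylcholine
    LPE = "LPE"  # lysophosphatidylethanolamine
    PA = "PA"  # phosphatidic acid
    PC = "PC"  # phosphatidylcholine
    PE = "PE"  # phosphatidylethanolamine
    PG = "PG"  # phosphatidylglycerol
    PI = "PI"  # phosphatidylinositol
    PS = "PS"  # phosphatidylserine
    SPH = "SPH"  # sphingoid base
    TG = "TG"  # triacylglycerol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class LipidNameError(ValueError):
    """Raised when a species-level lipid name cannot be parsed."""


@dataclass(frozen=True, order=True)
class LipidSpecies:
    """A species-level lipid identity.

    Parameters
    ----------
    lipid_class
        One of the 15 supported classes.
    carbons
        Total fatty acyl carbons (non-negative).
    double_bonds
        Total fatty acyl double bonds (non-negative).
    isomer_index
        Optional 1-based chromatographic elution-order index; present only
        when the species resolves into more than one chromatographic isomer.
    labeled
        True for the uniformly 13C-labeled form (internal standard).
    """

    lipid_class: LipidClass
    carbons: int
    double_bonds: int
    isomer_index: Optional[int] = None
    labeled: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 0:
            raise ValueError("carbons must be non-negative")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be non-negative")
        if self.isomer_index is not None and self.isomer_index < 1:
            raise ValueError("isomer_index must be a positive integer")

    @property
    def name(self) -> str:
        """Canonical species name, e.g. ``PC 34:2`` or ``TG 48:2 (2)``."""
        base = f"{self.lipid_class.value} {self.carbons}:{self.double_bonds}"
        if self.isomer_index is not None:
            base += f" ({self.isomer_index})"
        return base

    def __str__(self) -> str:
        return self.name

    def key(self) -> str:
        """Identity key used for matching (name; labeling carried separately)."""
        return self.name

    def with_label(self, labeled: bool) -> "LipidSpecies":
        return LipidSpecies(
            self.lipid_class, self.carbons, self.double_bonds, self.isomer_index, labeled
        )


@dataclass(frozen=True)
class Adduct:
    """A singly charged ionized form of a neutral lipid.

    ``mass_delta`` is the signed charge-carrier mass change in Da, so that
    ``m/z = neutral_mass + mass_delta`` for the singly charged ion.
    """

    name: str
    polarity: str  # "positive" or "negative"
    mass_delta: float

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


#: The five supported adduct types, keyed by canonical name (ASCII hyphen-minus).
ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", "positive", +PROTON_MASS),
    "[M+NH4]+": Adduct("[M+NH4]+", "positive", +18.033823),
    "[M+Na]+": Adduct("[M+Na]+", "positive", +22.989218),
    "[M-H]-": Adduct("[M-H]-", "negative", -PROTON_MASS),
    "[M+HCOO]-": Adduct("[M+HCOO]-", "negative", +44.998201),
}

_ADDUCT_ALIASES = {
    # unicode minus / en-dash variants occasionally found in exports
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M+HCOO]−": "[M+HCOO]-",
    "[M + H]+": "[M+H]+",
    "[M + NH4]+": "[M+NH4]+",
    "[M + Na]+": "[M+Na]+",
    "[M - H]-": "[M-H]-",
    "[M + HCOO]-": "[M+HCOO]-",
}


def get_adduct(name: str) -> Adduct:
    """Look up an adduct by name, tolerating common typographic variants."""
    name = name.strip()
    name = _ADDUCT_ALIASES.get(name, name)
    try:
        return ADDUCTS[name]
    except KeyError:
        raise LipidNameError(f"unknown adduct {name!r}; supported: {sorted(ADDUCTS)}") from None


_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s+(?P<c>\d+):(?P<db>\d+)(?:\s*\((?P<iso>\d+)\))?\s*$"
)


def parse_lipid_name(name: str, labeled: bool = False) -> LipidSpecies:
    """Parse a species-level lipid name like ``PC 34:2`` or ``TG 48:2 (2)``.

    The labeling status is not part of the name; pass it through ``labeled``.

    Raises
    ------
    LipidNameError
        If the class token is unknown or the carbons:double-bonds part is
        malformed.
    """
    if not name or not name.strip():
        raise LipidNameError("empty lipid name")
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidNameError(f"malformed lipid name {name!r}; expected 'CLASS C:DB [(i)]'")
    cls_token = m.group("cls")
    try:
        cls = LipidClass(cls_token)
    except ValueError:
        raise LipidNameError(
            f"unknown lipid class {cls_token!r} in {name!r}; "
            f"supported: {[c.value for c in LipidClass]}"
        ) from None
    iso = m.group("iso")
    return LipidSpecies(
        lipid_class=cls,
        carbons=int(m.group("c")),
        double_bonds=int(m.group("db")),
        isomer_index=int(iso) if iso is not None else None,
        labeled=labeled,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical text form; inverse of :func:`parse_lipid_name`."""
    return species.name


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of the singly charged adduct of a neutral of mass ``neutral_mass``."""
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return neutral_mass + adduct.mass_delta


def u13c_mass_shift(n_carbons: int) -> float:
    """Mass shift (Da) of uniform 13C labeling of ``n_carbons`` carbon atoms."""
    if n_carbons < 0:
        raise ValueError("n_carbons must be non-negative")
    return n_carbons * C13_MASS_SHIFT


def ppm_error(measured_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical_mz must be positive")
    return (measured_mz - theoretical_mz) / theoretical_mz * 1e6


def isotopologue_apparent_shift(
    m_light: float, m_heavy: float, gas_mass: float = N2_MASS
) -> float:
    """Apparent fractional CCS shift between isotopologues from reduced mass.

    In drift-type IM the measured quantity scales with ``sqrt(mu)`` where
    ``mu = m * M / (m + M)`` is the ion/buffer-gas reduced mass.  Two
    isotopologues of identical structure therefore show a small apparent shift
    of ``sqrt(mu_heavy / mu_light) - 1`` when their mobilities are converted
    to CCS without accounting for the mass difference.  This is a diagnostic
    utility (it rationalizes the small labeled-vs-unlabeled shift seen at
    moderate IM resolution), not a correction applied anywhere.
    """
    if m_light <= 0 or m_heavy <= 0 or gas_mass <= 0:
        raise ValueError("all masses must be positive")
    if m_heavy < m_light:
        raise ValueError("m_heavy must be >= m_light")
    mu_light = m_light * gas_mass / (m_light + gas_mass)
    mu_heavy = m_heavy * gas_mass / (m_heavy + gas_mass)
    return (mu_heavy / mu_light) ** 0.5 - 1.0
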