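"""Reference CCS library: data model, CSV I/O, curation and validation.

The reference library holds drift-tube CCS values in nitrogen (DTCCS_N2) for
U13C-labeled lipids, one row per (species, adduct).  Libraries are built from
replicate observations across a dilution series by a four-criterion curation
pipeline:

1. mass accuracy: every observation of the group within |ppm| <= 5;
2. detection in at least two distinct dilutions;
3. coelution of adducts: the group's mean retention time must sit within a
   tolerance of the species-level median RT across all its adducts (both
   polarities pooled);
4. CCS repeatability: relative standard deviation < 1%.

Filters are applied in this order and a rejected group is reported with the
first criterion it fails.  Retained groups become library entries with the
arithmetic-mean CCS as the reference value.

A curated library is additionally validated against the equivalent carbon
number (ECN) trend transferred to the CCS dimension: within a lipid
class-adduct combination, longer acyl chains must give larger CCS and more
double bonds smaller CCS.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .lipids import (
    Adduct,
    LipidSpecies,
    get_adduct,
    parse_lipid_name,
    ppm_error,
)

__all__ = [
    "Observation",
    "LibraryEntry",
    "CuratedLibrary",
    "CurationThresholds",
    "Rejection",
    "LibrarySchemaError",
    "LibraryValidationError",
    "LIBRARY_COLUMNS",
    "OBSERVATION_COLUMNS",
    "read_library",
    "write_library",
    "read_observations",
    "write_observations",
    "curate_library",
    "ecn_trend_validate",
    "library_summary",
]


LIBRARY_COLUMNS = [
    "lipid_name",
    "lipid_class",
    "carbons",
    "double_bonds",
    "isomer",
    "adduct",
    "polarity",
    "label",
    "mz_theoretical",
    "dtccs_n2",
    "ccs_rsd_pct",
    "n_detections",
]

OBSERVATION_COLUMNS = [
    "file_id",
    "dilution_id",
    "lipid_name",
    "adduct",
    "polarity",
    "label",
    "mz_measured",
    "mz_theoretical",
    "rt_min",
    "ccs",
]


class LibrarySchemaError(ValueError):
    """A CSV does not conform to the expected column schema."""


class LibraryValidationError(ValueError):
    """A row violates a library invariant (positivity, uniqueness, RSD...)."""


@dataclass(frozen=True)
class Observation:
    """One observed lipid-adduct ion in one file of a dilution series."""

    file_id: str
    dilution_id: str
    species: LipidSpecies
    adduct: Adduct
    measured_mz: float
    theoretical_mz: float
    rt: float
    ccs: float

    def __post_init__(self) -> None:
        if self.ccs <= 0:
            raise LibraryValidationError(f"ccs must be positive, got {self.ccs}")
        if self.rt < 0:
            raise LibraryValidationError(f"rt must be non-negative, got {self.rt}")


@dataclass(frozen=True)
class LibraryEntry:
    """One (species, adduct) reference row with its DTCCS_N2 value."""

    species: LipidSpecies
    adduct: Adduct
    theoretical_mz: float
    dtccs: float
    ccs_rsd: float
    n_detections: int

    def __post_init__(self) -> None:
        if self.dtccs <= 0:
            raise LibraryValidationError(f"dtccs must be positive, got {self.dtccs}")
        if not self.ccs_rsd < 1.0:
            raise LibraryValidationError(
                f"ccs_rsd must be < 1% for a curated entry, got {self.ccs_rsd}"
            )
        if self.n_detections < 2:
            raise LibraryValidationError(
                f"n_detections must be >= 2, got {self.n_detections}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.species.name, self.adduct.name)


@dataclass
class CuratedLibrary:
    """A validated set of reference entries plus provenance text."""

    entries: list[LibraryEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.key in seen:
                raise LibraryValidationError(f"duplicate library key {e.key}")
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_key(self) -> dict[tuple[str, str], LibraryEntry]:
        return {e.key: e for e in self.entries}

    def classes(self) -> list[str]:
        return sorted({e.species.lipid_class.value for e in self.entries})

    def subset(self, lipid_class: str, adduct: str) -> list[LibraryEntry]:
        return [
            e
            for e in self.entries
            if e.species.lipid_class.value == lipid_class and e.adduct.name == adduct
        ]


# ---------------------------------------------------------------------------
# CSV I/O


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LibrarySchemaError(f"{what} is missing columns {missing}")


def library_to_frame(library: CuratedLibrary) -> pd.DataFrame:
    rows = []
    for e in library.entries:
        s = e.species
        rows.append(
            {
                "lipid_name": s.name,
                "lipid_class": s.lipid_class.value,
                "carbons": s.carbons,
                "double_bonds": s.double_bonds,
                "isomer": s.isomer_index if s.isomer_index is not None else "",
                "adduct": e.adduct.name,
                "polarity": e.adduct.polarity,
                "label": "U13C" if s.labeled else "12C",
                "mz_theoretical": round(e.theoretical_mz, 4),
                "dtccs_n2": round(e.dtccs, 4),
                "ccs_rsd_pct": round(e.ccs_rsd, 4),
                "n_detections": e.n_detections,
            }
        )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(library: CuratedLibrary, path: str | Path, header: str | None = None) -> None:
    """Write a library CSV; optional '#'-prefixed provenance header block."""
    path = Path(path)
    df = library_to_frame(library)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_library(path: str | Path) -> CuratedLibrary:
    """Read and validate a library CSV.

    Raises :class:`LibrarySchemaError` for missing columns and
    :class:`LibraryValidationError` for invariant violations (non-positive
    CCS, RSD >= 1%, duplicate (species, adduct) keys...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"isomer": "string"})
    _require_columns(df, LIBRARY_COLUMNS, f"library CSV {path.name}")
    entries = []
    for _, row in df.iterrows():
        labeled = str(row["label"]).strip().upper() == "U13C"
        species = parse_lipid_name(str(row["lipid_name"]), labeled=labeled)
        if species.lipid_class.value != str(row["lipid_class"]):
            raise LibraryValidationError(
                f"lipid_name {row['lipid_name']!r} inconsistent with "
                f"lipid_class {row['lipid_class']!r}"
            )
        entries.append(
            LibraryEntry(
                species=species,
                adduct=get_adduct(str(row["adduct"])),
                theoretical_mz=float(row["mz_theoretical"]),
                dtccs=float(row["dtccs_n2"]),
                ccs_rsd=float(row["ccs_rsd_pct"]),
                n_detections=int(row["n_detections"]),
            )
        )
    return CuratedLibrary(entries=entries, provenance=str(path))


def observations_to_frame(observations: Iterable[Observation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(
            {
                "file_id": o.file_id,
                "dilution_id": o.dilution_id,
                "lipid_name": o.species.name,
                "adduct": o.adduct.name,
                "polarity": o.adduct.polarity,
                "label": "U13C" if o.species.labeled else "12C",
                "mz_measured": round(o.measured_mz, 4),
                "mz_theoretical": round(o.theoretical_mz, 4),
                "rt_min": round(o.rt, 3),
                "ccs": round(o.ccs, 4),
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def write_observations(
    observations: Iterable[Observation], path: str | Path, header: str | None = None
) -> None:
    path = Path(path)
    df = observations_to_frame(observations)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_observations(path: str | Path) -> list[Observation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, OBSERVATION_COLUMNS, f"observation CSV {path.name}")
    observations = []
    for _, row in df.iterrows():
        labeled = str(row["label"]).strip().upper() == "U13C"
        observations.append(
            Observation(
                file_id=str(row["file_id"]),
                dilution_id=str(row["dilution_id"]),
                species=parse_lipid_name(str(row["lipid_name"]), labeled=labeled),
                adduct=get_adduct(str(row["adduct"])),
                measured_mz=float(row["mz_measured"]),
                theoretical_mz=float(row["mz_theoretical"]),
                rt=float(row["rt_min"]),
                ccs=float(row["ccs"]),
            )
        )
    return observations


# ---------------------------------------------------------------------------
# Curation


@dataclass(frozen=True)
class CurationThresholds:
    """Curation filter thresholds; defaults are the published criteria."""

    ppm_max: float = 5.0  # inclusive: |ppm| <= ppm_max passes
    min_detections: int = 2  # distinct dilutions required
    rt_tolerance: float = 0.1  # minutes, vs species-level median RT
    rsd_max: float = 1.0  # exclusive: RSD < rsd_max passes


#: Rejection reasons in filter order.
REASON_MASS_ACCURACY = "mass_accuracy"
REASON_MIN_DETECTIONS = "min_detections"
REASON_COELUTION = "coelution"
REASON_CCS_RSD = "ccs_rsd"


@dataclass(frozen=True)
class Rejection:
    """One rejected (species, adduct) group with its primary reason."""

    species_name: str
    adduct: str
    reason: str
    detail: str = ""


def _group_observations(
    observations: Iterable[Observation],
) -> dict[tuple[str, str], list[Observation]]:
    groups: dict[tuple[str, str], list[Observation]] = {}
    for o in observations:
        groups.setdefault((o.species.name, o.adduct.name), []).append(o)
    return groups


def curate_library(
    observations: Iterable[Observation],
    thresholds: CurationThresholds = CurationThresholds(),
    provenance: str = "",
) -> tuple[CuratedLibrary, list[Rejection]]:
    """Apply the four curation criteria and build a reference library.

    Returns the curated library and the rejection report.  Each rejected
    (species, adduct) group carries exactly one primary reason: the first
    criterion it fails in the order mass accuracy -> minimum detections ->
    adduct coelution -> CCS RSD.
    """
    groups = _group_observations(observations)
    if not groups:
        return CuratedLibrary(entries=[], provenance=provenance), []

    # Species-level median RT across all (species, adduct) groups, both
    # polarities pooled, used by the coelution criterion.
    group_rt = {key: statistics.fmean(o.rt for o in obs) for key, obs in groups.items()}
    species_rts: dict[str, list[float]] = {}
    for (name, _adduct), rt in group_rt.items():
        species_rts.setdefault(name, []).append(rt)
    species_median_rt = {name: statistics.median(rts) for name, rts in species_rts.items()}

    entries: list[LibraryEntry] = []
    rejections: list[Rejection] = []
    for key in sorted(groups):
        name, adduct_name = key
        obs = groups[key]

        bad_ppm = [
            ppm_error(o.measured_mz, o.theoretical_mz)
            for o in obs
            if abs(ppm_error(o.measured_mz, o.theoretical_mz)) > thresholds.ppm_max
        ]
        if bad_ppm:
            rejections.append(
                Rejection(name, adduct_name, REASON_MASS_ACCURACY,
                          f"max |ppm| = {max(abs(p) for p in bad_ppm):.2f}")
            )
            continue

        n_dilutions = len({o.dilution_id for o in obs})
        if n_dilutions < thresholds.min_detections:
            rejections.append(
                Rejection(name, adduct_name, REASON_MIN_DETECTIONS,
                          f"seen in {n_dilutions} dilution(s)")
            )
            continue

        dev = abs(group_rt[key] - species_median_rt[name])
        if dev > thresholds.rt_tolerance:
            rejections.append(
                Rejection(name, adduct_name, REASON_COELUTION,
                          f"|RT - species median| = {dev:.3f} min")
            )
            continue

        ccs_values = [o.ccs for o in obs]
        mean_ccs = statistics.fmean(ccs_values)
        rsd = (
            statistics.stdev(ccs_values) / mean_ccs * 100.0
            if len(ccs_values) > 1
            else 0.0
        )
        if not rsd < thresholds.rsd_max:
            rejections.append(
                Rejection(name, adduct_name, REASON_CCS_RSD, f"RSD = {rsd:.3f}%")
            )
            continue

        entries.append(
            LibraryEntry(
                species=obs[0].species,
                adduct=obs[0].adduct,
                theoretical_mz=obs[0].theoretical_mz,
                dtccs=mean_ccs,
                ccs_rsd=rsd,
                n_detections=n_dilutions,
            )
        )
    return CuratedLibrary(entries=entries, provenance=provenance), rejections


# ---------------------------------------------------------------------------
# ECN validation and summary


def ecn_trend_validate(
    library: CuratedLibrary, lipid_class: str, adduct: str
) -> list[tuple[LibraryEntry, LibraryEntry]]:
    """Find ECN-trend violations within one lipid class-adduct combination.

    Returns ordered entry pairs ``(e1, e2)`` where either the chain-length
    trend (same double bonds, more carbons must mean larger CCS) or the
    unsaturation trend (same carbons, more double bonds must mean smaller
    CCS) is violated.  An empty list means the combination is consistent.
    Isomer pairs (same carbons and double bonds) are not compared.
    """
    entries = library.subset(lipid_class, adduct)
    violations: list[tuple[LibraryEntry, LibraryEntry]] = []
    for e1 in entries:
        for e2 in entries:
            s1, s2 = e1.species, e2.species
            if s1.double_bonds == s2.double_bonds and s1.carbons < s2.carbons:
                if e1.dtccs >= e2.dtccs:
                    violations.append((e1, e2))
            elif s1.carbons == s2.carbons and s1.double_bonds < s2.double_bonds:
                if e1.dtccs <= e2.dtccs:
                    violations.append((e1, e2))
    return violations


def ecn_trend_validate_all(
    library: CuratedLibrary,
) -> dict[tuple[str, str], list[tuple[LibraryEntry, LibraryEntry]]]:
    """ECN validation for every class-adduct combination; only non-empty kept."""
    combos = sorted({(e.species.lipid_class.value, e.adduct.name) for e in library.entries})
    out = {}
    for cls, adduct in combos:
        v = ecn_trend_validate(library, cls, adduct)
        if v:
            out[(cls, adduct)] = v
    return out


def library_summary(library: CuratedLibrary) -> dict:
    """Composition summary: counts and m/z / CCS ranges.

    For an empty library all counts are 0 and the ranges are ``None``.
    """
    if not library.entries:
        return {
            "n_entries": 0,
            "n_species": 0,
            "n_classes": 0,
            "n_adducts": 0,
            "mz_min": None,
            "mz_max": None,
            "dtccs_min": None,
            "dtccs_max": None,
        }
    mzs = [e.theoretical_mz for e in library.entries]
    ccs = [e.dtccs for e in library.entries]
    return {
        "n_entries": len(library.entries),
        "n_species": len({e.species.name for e in library.entries}),
        "n_classes": len({e.species.lipid_class.value for e in library.entries}),
        "n_adducts": len({e.adduct.name for e in library.entries}),
        "mz_min": min(mzs),
        "mz_max": max(mzs),
        "dtccs_min": min(ccs),
        "dtccs_max": max(ccs),
    }
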