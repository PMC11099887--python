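"""CCS bias monitoring against the reference library.

Measured CCS values (e.g. TIMCCS_N2 from an externally calibrated trapped-ion
mobility instrument) are matched to reference DTCCS_N2 entries by canonical
species name (including the isomer elution index) and adduct, and the signed
percent bias

    bias% = (CCS_measured - CCS_reference) / CCS_reference * 100

is summarized per lipid class / adduct / polarity and rolled up per ionization
mode.  Matching is name-based (targeted workflow); only U13C-labeled measured
ions are matched for QC purposes, since the reference library contains labeled
lipids.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd

from .library import CuratedLibrary, LibraryEntry, LibrarySchemaError
from .lipids import Adduct, LipidSpecies, get_adduct, parse_lipid_name

__all__ = [
    "MeasuredIon",
    "MatchedPair",
    "BiasSummary",
    "MEASURED_COLUMNS",
    "read_measured",
    "write_measured",
    "ccs_bias_percent",
    "match_to_library",
    "mean_measured",
    "summarize_bias",
    "bias_summary_frame",
]

MEASURED_COLUMNS = [
    "file_id",
    "lipid_name",
    "adduct",
    "polarity",
    "label",
    "mz_measured",
    "rt_min",
    "ccs_measured",
]


@dataclass(frozen=True)
class MeasuredIon:
    """One observed lipid-adduct ion with its measured CCS."""

    file_id: str
    species: LipidSpecies
    adduct: Adduct
    measured_mz: float
    rt: float
    ccs_measured: float

    def __post_init__(self) -> None:
        if self.ccs_measured <= 0:
            raise ValueError(f"ccs_measured must be positive, got {self.ccs_measured}")

    @property
    def labeled(self) -> bool:
        return self.species.labeled

    @property
    def key(self) -> tuple[str, str]:
        return (self.species.name, self.adduct.name)


@dataclass(frozen=True)
class MatchedPair:
    """A measured ion paired with its library reference entry."""

    measured: MeasuredIon
    reference: LibraryEntry

    @property
    def bias_pct(self) -> float:
        return ccs_bias_percent(self.measured.ccs_measured, self.reference.dtccs)

    @property
    def lipid_class(self) -> str:
        return self.reference.species.lipid_class.value

    @property
    def adduct(self) -> str:
        return self.reference.adduct.name

    @property
    def polarity(self) -> str:
        return self.reference.adduct.polarity


@dataclass(frozen=True)
class BiasSummary:
    """Grouped signed/absolute CCS-bias statistics."""

    group: tuple  # e.g. (lipid_class, adduct, polarity) or (polarity,)
    n: int
    mean_bias: float
    mean_abs_bias: float
    min_bias: float
    max_bias: float


@dataclass(frozen=True)
class UnmatchedIon:
    """A measured ion that could not be paired, with the reason."""

    measured: MeasuredIon
    reason: str  # "not_in_library" | "ambiguous_isomer" | "unlabeled"


def ccs_bias_percent(ccs_measured: float, ccs_reference: float) -> float:
    """Signed percent deviation of a measured CCS from its reference.

    Positive means the instrument reads larger than the reference.
    """
    if ccs_measured <= 0 or ccs_reference <= 0:
        raise ValueError("CCS values must be positive")
    return (ccs_measured - ccs_reference) / ccs_reference * 100.0


# ---------------------------------------------------------------------------
# I/O


def read_measured(path: str | Path) -> list[MeasuredIon]:
    """Read a measured-CCS CSV (targeted, Skyline-style export)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MEASURED_COLUMNS if c not in df.columns]
    if missing:
        raise LibrarySchemaError(f"measured CSV {path.name} is missing columns {missing}")
    ions = []
    for _, row in df.iterrows():
        labeled = str(row["label"]).strip().upper() == "U13C"
        ions.append(
            MeasuredIon(
                file_id=str(row["file_id"]),
                species=parse_lipid_name(str(row["lipid_name"]), labeled=labeled),
                adduct=get_adduct(str(row["adduct"])),
                measured_mz=float(row["mz_measured"]),
                rt=float(row["rt_min"]),
                ccs_measured=float(row["ccs_measured"]),
            )
        )
    return ions


def measured_to_frame(ions: Iterable[MeasuredIon]) -> pd.DataFrame:
    rows = []
    for m in ions:
        rows.append(
            {
                "file_id": m.file_id,
                "lipid_name": m.species.name,
                "adduct": m.adduct.name,
                "polarity": m.adduct.polarity,
                "label": "U13C" if m.labeled else "12C",
                "mz_measured": round(m.measured_mz, 4),
                "rt_min": round(m.rt, 3),
                "ccs_measured": round(m.ccs_measured, 4),
            }
        )
    return pd.DataFrame(rows, columns=MEASURED_COLUMNS)


def write_measured(
    ions: Iterable[MeasuredIon], path: str | Path, header: str | None = None
) -> None:
    df = measured_to_frame(ions)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Matching and summaries


def mean_measured(ions: Iterable[MeasuredIon]) -> list[MeasuredIon]:
    """Average measured CCS (and m/z, RT) per ion across files.

    Mirrors running the QC on the mean of all measurement files instead of
    per file; the resulting ions carry ``file_id='mean'``.
    """
    groups: dict[tuple[str, str, bool], list[MeasuredIon]] = {}
    order: list[tuple[str, str, bool]] = []
    for m in ions:
        k = (m.species.name, m.adduct.name, m.labeled)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(m)
    out = []
    for k in order:
        ms = groups[k]
        out.append(
            MeasuredIon(
                file_id="mean",
                species=ms[0].species,
                adduct=ms[0].adduct,
                measured_mz=statistics.fmean(m.measured_mz for m in ms),
                rt=statistics.fmean(m.rt for m in ms),
                ccs_measured=statistics.fmean(m.ccs_measured for m in ms),
            )
        )
    return out


def match_to_library(
    measured: Iterable[MeasuredIon], library: CuratedLibrary
) -> tuple[list[MatchedPair], list[UnmatchedIon]]:
    """Match labeled measured ions to library entries by (name, adduct).

    Unlabeled ions are not matched (the library holds labeled lipids); they
    are reported as unmatched with reason ``unlabeled`` so callers can still
    carry them into correction application.  A measured ion without an isomer
    index whose species resolves to more than one isomer in the library is
    excluded as ambiguous rather than guessed.
    """
    by_key = library.by_key()
    # species-form key without isomer index -> candidate entries
    isomer_groups: dict[tuple[str, int, int, str], list[LibraryEntry]] = {}
    for e in library.entries:
        s = e.species
        if s.isomer_index is not None:
            isomer_groups.setdefault(
                (s.lipid_class.value, s.carbons, s.double_bonds, e.adduct.name), []
            ).append(e)

    pairs: list[MatchedPair] = []
    unmatched: list[UnmatchedIon] = []
    for m in measured:
        if not m.labeled:
            unmatched.append(UnmatchedIon(m, "unlabeled"))
            continue
        entry = by_key.get((m.species.name, m.adduct.name))
        if entry is not None:
            pairs.append(MatchedPair(measured=m, reference=entry))
            continue
        s = m.species
        if s.isomer_index is None:
            candidates = isomer_groups.get(
                (s.lipid_class.value, s.carbons, s.double_bonds, m.adduct.name), []
            )
            if len(candidates) > 1:
                unmatched.append(UnmatchedIon(m, "ambiguous_isomer"))
                continue
            if len(candidates) == 1:
                pairs.append(MatchedPair(measured=m, reference=candidates[0]))
                continue
        unmatched.append(UnmatchedIon(m, "not_in_library"))
    return pairs, unmatched


GroupBy = Literal["class_adduct", "mode"]


def _summary(group: tuple, biases: list[float]) -> BiasSummary:
    return BiasSummary(
        group=group,
        n=len(biases),
        mean_bias=statistics.fmean(biases),
        mean_abs_bias=statistics.fmean(abs(b) for b in biases),
        min_bias=min(biases),
        max_bias=max(biases),
    )


def summarize_bias(
    pairs: Iterable[MatchedPair], group_by: GroupBy = "class_adduct"
) -> list[BiasSummary]:
    """Grouped bias statistics.

    ``class_adduct`` groups by (lipid class, adduct, polarity); ``mode``
    rolls up to ionization mode (positive vs negative), each matched ion
    weighted equally.
    """
    groups: dict[tuple, list[float]] = {}
    for p in pairs:
        if group_by == "class_adduct":
            key = (p.lipid_class, p.adduct, p.polarity)
        elif group_by == "mode":
            key = (p.polarity,)
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown group_by {group_by!r}")
        groups.setdefault(key, []).append(p.bias_pct)
    return [_summary(k, v) for k, v in sorted(groups.items())]


def bias_summary_frame(summaries: Iterable[BiasSummary]) -> pd.DataFrame:
    """Tabular form of bias summaries for CSV output."""
    rows = []
    for s in summaries:
        row = {f"group_{i + 1}": g for i, g in enumerate(s.group)}
        row.update(
            n=s.n,
            mean_bias_pct=round(s.mean_bias, 4),
            mean_abs_bias_pct=round(s.mean_abs_bias, 4),
            min_bias_pct=round(s.min_bias, 4),
            max_bias_pct=round(s.max_bias, 4),
        )
        rows.append(row)
    return pd.DataFrame(rows)
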