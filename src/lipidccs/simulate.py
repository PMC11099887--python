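"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the shapes of the real study data without any
download: a reference library whose CCS values follow a per-class ECN model
(longer chains larger CCS, more double bonds smaller CCS), a replicate
observation table across a dilution series (reference-instrument data used
for library curation), and a measured-CCS table from a second instrument
whose values carry a known affine bias per lipid class-adduct combination
plus multiplicative Gaussian noise.  The injected bias is parameterized in
the correction orientation, i.e. by the affine map that takes a measured CCS
back to the truth:

    CCS_true = slope * CCS_biased   + intercept
    CCS_measured = CCS_biased + N(0, sd% * CCS_true)
               = (CCS_true - intercept) / slope + noise

so a noise-free fit of reference on measured recovers (slope, intercept)
exactly, and the injected pair is directly the ground-truth correction
function.

Defaults mirror the study conditions: the 10 correctable lipid classes with
their typical adducts, eight labeled lipids per class-adduct combination,
an affine bias of about +1% (correction slope 0.988, intercept 0.5 A^2,
giving a measured bias within the -0.31..1.08% per-class range reported for
real cross-platform data), 0.2%
measurement noise (under the 1% repeatability criterion), and three
dilutions.  Curation-filter violations (high ppm error, single-dilution
detection, non-coeluting adduct, high CCS RSD) can be injected in known
places; the emitted truth records exactly which groups must be rejected and
why.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .bias import MeasuredIon, write_measured
from .library import (
    CuratedLibrary,
    LibraryEntry,
    Observation,
    write_library,
    write_observations,
)
from .library import (
    REASON_CCS_RSD,
    REASON_COELUTION,
    REASON_MASS_ACCURACY,
    REASON_MIN_DETECTIONS,
)
from .lipids import ADDUCTS, C13_MASS_SHIFT, LipidClass, LipidSpecies

__all__ = ["SimulationConfig", "SimulationTruth", "SimulatedDataset", "simulate_dataset"]


#: Default adduct coverage: the 10 correctable classes.
DEFAULT_CLASS_ADDUCTS: dict[str, tuple[str, ...]] = {
    "Cer": ("[M+H]+", "[M-H]-"),
    "DG": ("[M+NH4]+",),
    "HexCer": ("[M+H]+", "[M+HCOO]-"),
    "LPC": ("[M+H]+",),
    "PA": ("[M-H]-",),
    "PC": ("[M+H]+", "[M+Na]+", "[M+HCOO]-"),
    "PE": ("[M+H]+", "[M-H]-"),
    "PI": ("[M-H]-",),
    "PS": ("[M-H]-",),
    "TG": ("[M+NH4]+",),
}

#: Starting total acyl carbon count per class for generated species.
_CLASS_C0 = {
    "Cer": 34, "DG": 32, "HexCer": 34, "LPC": 16, "PA": 32,
    "PC": 30, "PE": 32, "PI": 32, "PS": 34, "TG": 48,
    "AcCa": 14, "Co": 41, "LPE": 16, "PG": 34, "SPH": 16,
}

_ADDUCT_CCS_OFFSET = {
    "[M+H]+": 0.0, "[M+NH4]+": 1.5, "[M+Na]+": 4.0, "[M-H]-": -2.0, "[M+HCOO]-": 3.0,
}


@dataclass(frozen=True)
class EcnCoefficients:
    """Per-class affine ECN model for true CCS values."""

    base: float  # A^2 at zero carbons / double bonds
    per_carbon: float  # A^2 per acyl carbon, must be > 0
    per_double_bond: float  # A^2 decrement per double bond, must be > 0

    def __post_init__(self) -> None:
        if self.per_carbon <= 0:
            raise ValueError("per_carbon increment must be positive")
        if self.per_double_bond <= 0:
            raise ValueError("per_double_bond decrement must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset."""

    classes: tuple[str, ...] = tuple(sorted(DEFAULT_CLASS_ADDUCTS))
    class_adducts: Optional[dict[str, tuple[str, ...]]] = None
    n_lipids: int = 8  # labeled lipids per class-adduct combination
    ecn: Optional[dict[str, EcnCoefficients]] = None
    bias_slope: float = 0.988  # true correction slope: true = s*measured + b
    bias_intercept: float = 0.5  # A^2; together about +1% measured bias
    bias_overrides: Optional[dict[tuple[str, str], tuple[float, float]]] = None
    noise_sd_pct: float = 0.2  # multiplicative CCS noise, percent of true
    n_dilutions: int = 3
    n_files: int = 3
    include_unlabeled: bool = True
    n_high_ppm: int = 0
    n_single_dilution: int = 0
    n_non_coeluting: int = 0
    n_high_rsd: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids < 1:
            raise ValueError("n_lipids must be >= 1")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        if self.n_dilutions < 1 or self.n_files < 1:
            raise ValueError("n_dilutions and n_files must be >= 1")
        for v in (self.n_high_ppm, self.n_single_dilution,
                  self.n_non_coeluting, self.n_high_rsd):
            if v < 0:
                raise ValueError("violation counts must be >= 0")

    def resolved_adducts(self) -> dict[str, tuple[str, ...]]:
        if self.class_adducts is not None:
            return {c: tuple(a) for c, a in self.class_adducts.items()}
        return {c: DEFAULT_CLASS_ADDUCTS.get(c, ("[M+H]+",)) for c in self.classes}

    def ecn_for(self, cls: str, index: int) -> EcnCoefficients:
        if self.ecn is not None and cls in self.ecn:
            return self.ecn[cls]
        return EcnCoefficients(base=196.0 + 4.0 * (index % 5), per_carbon=2.3,
                               per_double_bond=1.6)

    def bias_for(self, cls: str, adduct: str) -> tuple[float, float]:
        if self.bias_overrides is not None and (cls, adduct) in self.bias_overrides:
            return self.bias_overrides[(cls, adduct)]
        return (self.bias_slope, self.bias_intercept)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the tables."""

    true_ccs: dict[tuple[str, str], float]  # (species name, adduct) -> A^2
    bias: dict[tuple[str, str], tuple[float, float]]  # (class, adduct) -> (slope, b)
    expected_rejections: dict[tuple[str, str], str]  # group key -> reason
    seed: int


@dataclass
class SimulatedDataset:
    library: CuratedLibrary
    observations: list[Observation]
    measured: list[MeasuredIon]
    truth: SimulationTruth

    def write(self, outdir: str | Path, header: str | None = None) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "library": outdir / "library.csv",
            "observations": outdir / "observations.csv",
            "measured": outdir / "measured.csv",
        }
        write_library(self.library, paths["library"], header=header)
        write_observations(self.observations, paths["observations"], header=header)
        write_measured(self.measured, paths["measured"], header=header)
        return paths


def _species_grid(cls: str, n: int) -> list[LipidSpecies]:
    c0 = _CLASS_C0.get(cls, 30)
    out = []
    for i in range(n):
        out.append(
            LipidSpecies(
                lipid_class=LipidClass(cls),
                carbons=c0 + 2 * (i // 3),
                double_bonds=i % 3,
                labeled=True,
            )
        )
    return out


def _theoretical_mz(species: LipidSpecies, adduct_name: str) -> float:
    # simple additive neutral-mass model; labeled adds the uniform 13C shift
    neutral = 300.0 + 12.5 * species.carbons - 2.01565 * species.double_bonds
    if species.labeled:
        neutral += (species.carbons + 5) * C13_MASS_SHIFT
    return neutral + ADDUCTS[adduct_name].mass_delta


def _rt(species: LipidSpecies) -> float:
    return max(0.2, 1.5 + 0.08 * species.carbons - 0.15 * species.double_bonds)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate (library, observations, measured, truth) per the config."""
    rng = np.random.default_rng(config.seed)
    class_adducts = config.resolved_adducts()

    entries: list[LibraryEntry] = []
    true_ccs: dict[tuple[str, str], float] = {}
    bias: dict[tuple[str, str], tuple[float, float]] = {}
    for idx, cls in enumerate(sorted(class_adducts)):
        coeff = config.ecn_for(cls, idx)
        species_list = _species_grid(cls, config.n_lipids)
        for adduct_name in class_adducts[cls]:
            bias[(cls, adduct_name)] = config.bias_for(cls, adduct_name)
            for s in species_list:
                ccs = (
                    coeff.base
                    + coeff.per_carbon * s.carbons
                    - coeff.per_double_bond * s.double_bonds
                    + _ADDUCT_CCS_OFFSET[adduct_name]
                )
                true_ccs[(s.name, adduct_name)] = ccs
                entries.append(
                    LibraryEntry(
                        species=s,
                        adduct=ADDUCTS[adduct_name],
                        theoretical_mz=_theoretical_mz(s, adduct_name),
                        dtccs=ccs,
                        ccs_rsd=config.noise_sd_pct if config.noise_sd_pct < 1 else 0.2,
                        n_detections=config.n_dilutions,
                    )
                )
    library = CuratedLibrary(
        entries=entries,
        provenance=f"simulated dataset (seed={config.seed})",
    )

    # --- observation table (reference instrument, used for curation) -------
    observations: list[Observation] = []
    for e in entries:
        mz = e.theoretical_mz
        for d in range(1, config.n_dilutions + 1):
            noise = rng.normal(0.0, config.noise_sd_pct / 100.0 * e.dtccs)
            observations.append(
                Observation(
                    file_id=f"ref_{d:02d}",
                    dilution_id=f"D{d}",
                    species=e.species,
                    adduct=e.adduct,
                    measured_mz=mz,
                    theoretical_mz=mz,
                    rt=_rt(e.species),
                    ccs=e.dtccs + noise,
                )
            )

    expected_rejections = _inject_violations(observations, library, config)

    # --- measured table (biased instrument) --------------------------------
    measured: list[MeasuredIon] = []
    for e in entries:
        cls = e.species.lipid_class.value
        slope, intercept = bias[(cls, e.adduct.name)]
        forms = [e.species]
        if config.include_unlabeled:
            forms.append(e.species.with_label(False))
        for s in forms:
            mz = _theoretical_mz(s, e.adduct.name)
            biased = (e.dtccs - intercept) / slope
            for f in range(1, config.n_files + 1):
                noise = rng.normal(0.0, config.noise_sd_pct / 100.0 * e.dtccs)
                measured.append(
                    MeasuredIon(
                        file_id=f"file_{f:02d}",
                        species=s,
                        adduct=e.adduct,
                        measured_mz=mz,
                        rt=_rt(s),
                        ccs_measured=biased + noise,
                    )
                )

    truth = SimulationTruth(
        true_ccs=true_ccs,
        bias=bias,
        expected_rejections=expected_rejections,
        seed=config.seed,
    )
    return SimulatedDataset(
        library=library, observations=observations, measured=measured, truth=truth
    )


def _inject_violations(
    observations: list[Observation],
    library: CuratedLibrary,
    config: SimulationConfig,
) -> dict[tuple[str, str], str]:
    """Mutate the observation list in place; return expected rejections.

    Each violated species is used by exactly one violation type so that
    rejection reasons stay unambiguous.  A non-coeluting injection shifts the
    RT of one adduct of a multi-adduct species: with exactly two adducts the
    species median RT is their midpoint, so *both* groups fail coelution.
    """
    n_adducts: dict[str, list[str]] = {}
    for e in library.entries:
        n_adducts.setdefault(e.species.name, []).append(e.adduct.name)

    species_order = sorted(n_adducts)
    used: set[str] = set()
    expected: dict[tuple[str, str], str] = {}

    def take(predicate) -> str:
        for name in species_order:
            if name not in used and predicate(name):
                used.add(name)
                return name
        raise ValueError("not enough species to place the requested violations")

    def group_obs(name: str, adduct: str) -> list[Observation]:
        return [
            o
            for o in observations
            if o.species.name == name and o.adduct.name == adduct
        ]

    def swap(old: Observation, new: Observation) -> None:
        observations[observations.index(old)] = new

    for _ in range(config.n_high_ppm):
        name = take(lambda n: True)
        adduct = n_adducts[name][0]
        for o in group_obs(name, adduct):
            swap(o, replace(o, measured_mz=o.theoretical_mz * (1 + 8e-6)))
        expected[(name, adduct)] = REASON_MASS_ACCURACY

    for _ in range(config.n_single_dilution):
        name = take(lambda n: True)
        adduct = n_adducts[name][0]
        for o in group_obs(name, adduct):
            if o.dilution_id != "D1":
                observations.remove(o)
        expected[(name, adduct)] = REASON_MIN_DETECTIONS

    for _ in range(config.n_non_coeluting):
        name = take(lambda n: len(n_adducts[n]) >= 2)
        adduct = n_adducts[name][0]
        for o in group_obs(name, adduct):
            swap(o, replace(o, rt=o.rt + 0.5))
        expected[(name, adduct)] = REASON_COELUTION
        if len(n_adducts[name]) == 2:
            # median RT is the midpoint: the untouched adduct fails as well
            expected[(name, n_adducts[name][1])] = REASON_COELUTION

    for _ in range(config.n_high_rsd):
        name = take(lambda n: True)
        adduct = n_adducts[name][0]
        for i, o in enumerate(group_obs(name, adduct)):
            factor = 1.02 if i % 2 == 0 else 0.98
            swap(o, replace(o, ccs=o.ccs * factor))
        expected[(name, adduct)] = REASON_CCS_RSD

    return expected
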