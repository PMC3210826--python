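"""Inhalation dosimetry arithmetic.

Cumulative inhaled mass from an exposure regimen, regional deposited mass
from caller-supplied deposition fractions, tissue dose (mg analyte per kg
organ), particle surface-area dose, and lung retention percentage.

Deposition fractions are inputs: region-specific fractions of the inhaled
mass predicted by whatever aerosol deposition model the user trusts. The
module ships one documented example set (:data:`EXAMPLE_DEPOSITION_FRACTIONS`)
derived from a mouse whole-body inhalation study design (0.840 mg inhaled;
72.5 / 48 / 356 / 267 ug predicted in the pulmonary, tracheobronchial,
gastrointestinal and head regions).

Unit conventions are spelled out in function names and docstrings; all
quantities are degree-1 homogeneous in their mass argument and reported
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class ExposureRegimen:
    """An inhalation exposure schedule.

    days x hours_per_day x concentration (mg/m^3) x inhaled_volume_rate
    (m^3/hr) gives the cumulative inhaled mass in mg per animal.
    """

    days: float
    hours_per_day: float
    concentration_mg_m3: float
    inhaled_volume_rate_m3_hr: float

    def __post_init__(self) -> None:
        for name in (
            "days",
            "hours_per_day",
            "concentration_mg_m3",
            "inhaled_volume_rate_m3_hr",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Regimen of the motivating mouse study: 11 days, 1 hr/day, measured mean
#: aerosol concentration 42.4 mg/m^3, 0.0018 m^3 inhaled per hour.
MOUSE_STUDY_REGIMEN = ExposureRegimen(11, 1.0, 42.4, 0.0018)


@dataclass(frozen=True)
class DepositionFractions:
    """Fraction of the inhaled mass deposited in each respiratory region."""

    pulmonary: float = 0.0
    tracheobronchial: float = 0.0
    gastrointestinal: float = 0.0
    head: float = 0.0

    def __post_init__(self) -> None:
        for region, frac in self.as_dict().items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{region} fraction {frac} outside [0, 1]")
        if sum(self.as_dict().values()) > 1.0 + 1e-12:
            raise ValueError("deposition fractions sum to more than 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "pulmonary": self.pulmonary,
            "tracheobronchial": self.tracheobronchial,
            "gastrointestinal": self.gastrointestinal,
            "head": self.head,
        }


#: Example fractions implied by 72.5 / 48 / 356 / 267 ug regional deposition
#: out of 840 ug inhaled (a published mouse inhalation design).
EXAMPLE_DEPOSITION_FRACTIONS = DepositionFractions(
    pulmonary=72.5 / 840.0,
    tracheobronchial=48.0 / 840.0,
    gastrointestinal=356.0 / 840.0,
    head=267.0 / 840.0,
)


@dataclass(frozen=True)
class TissueDoseParams:
    """Organ and material parameters for tissue-dose reporting.

    ``material_mass_fraction`` scales a composite particle mass to its active
    material (e.g. the TiO2 weight fraction of a coated particle), and
    ``element_mass_fraction`` further scales to a measured element (e.g. Ti
    within TiO2). ``specific_surface_area_m2_g`` is the BET surface area.
    """

    organ_mass_mg: float
    material_mass_fraction: float = 1.0
    element_mass_fraction: float = 1.0
    specific_surface_area_m2_g: float | None = None

    def __post_init__(self) -> None:
        if self.organ_mass_mg <= 0:
            raise ValueError("organ mass must be > 0")
        for name in ("material_mass_fraction", "element_mass_fraction"):
            frac = getattr(self, name)
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if (
            self.specific_surface_area_m2_g is not None
            and self.specific_surface_area_m2_g <= 0
        ):
            raise ValueError("specific surface area must be > 0")


def cumulative_inhaled_mass_mg(regimen: ExposureRegimen) -> float:
    """Cumulative inhaled mass in mg per animal over the whole regimen."""
    return (
        regimen.days
        * regimen.hours_per_day
        * regimen.concentration_mg_m3
        * regimen.inhaled_volume_rate_m3_hr
    )


def regional_deposition_mg(
    total_mg: float, fractions: DepositionFractions
) -> dict[str, float]:
    """Per-region deposited mass (mg) plus the exhaled/cleared residual.

    Conserves mass exactly: the region masses and ``residual`` sum to
    ``total_mg``.
    """
    if total_mg < 0:
        raise ValueError("total mass must be >= 0")
    out = {region: total_mg * f for region, f in fractions.as_dict().items()}
    out["residual"] = total_mg - sum(out.values())
    return out


def tissue_dose_mg_per_kg(deposited_ug: float, organ_mass_mg: float) -> float:
    """Deposited mass (ug) per organ mass (mg), as mg analyte per kg tissue."""
    if organ_mass_mg <= 0:
        raise ValueError("organ mass must be > 0")
    if deposited_ug < 0:
        raise ValueError("deposited mass must be >= 0")
    # ug/mg == mg/g; x1000 -> mg/kg
    return deposited_ug / organ_mass_mg * 1000.0


def retention_percent(measured_mg_per_kg: float, predicted_mg_per_kg: float) -> float:
    """Measured tissue concentration as a percentage of the predicted dose."""
    if predicted_mg_per_kg <= 0:
        raise ValueError("predicted concentration must be > 0")
    if measured_mg_per_kg < 0:
        raise ValueError("measured concentration must be >= 0")
    return 100.0 * measured_mg_per_kg / predicted_mg_per_kg


def surface_area_dose_cm2(mass_ug: float, ssa_m2_per_g: float) -> float:
    """Particle surface area (cm^2) carried by ``mass_ug`` of material."""
    if ssa_m2_per_g <= 0:
        raise ValueError("specific surface area must be > 0")
    if mass_ug < 0:
        raise ValueError("mass must be >= 0")
    # ug -> g is 1e-6; m^2 -> cm^2 is 1e4
    return mass_ug * 1e-6 * ssa_m2_per_g * 1e4


def dose_report(
    regimen: ExposureRegimen,
    fractions: DepositionFractions,
    organ_mass_mg: float,
    ssa_m2_per_g: float | None = None,
    measured_mg_per_kg: float | None = None,
) -> dict[str, float]:
    """Labelled dosimetry summary with reporting-precision rounding.

    Masses in mg are rounded to 3 decimals; tissue doses (mg/kg) and
    retention (%) to the nearest integer; surface areas to 2 decimals.
    """
    total = cumulative_inhaled_mass_mg(regimen)
    regions = regional_deposition_mg(total, fractions)
    report: dict[str, float] = {"inhaled_mass_mg": round(total, 3)}
    for region, mass in regions.items():
        report[f"deposited_{region}_mg"] = round(mass, 3)
    pulmonary_ug = regions["pulmonary"] * 1000.0
    report["pulmonary_dose_mg_per_kg"] = round(
        tissue_dose_mg_per_kg(pulmonary_ug, organ_mass_mg)
    )
    bronchopulmonary_ug = (regions["pulmonary"] + regions["tracheobronchial"]) * 1000.0
    report["bronchopulmonary_dose_mg_per_kg"] = round(
        tissue_dose_mg_per_kg(bronchopulmonary_ug, organ_mass_mg)
    )
    if ssa_m2_per_g is not None:
        report["pulmonary_surface_area_cm2"] = round(
            surface_area_dose_cm2(pulmonary_ug, ssa_m2_per_g), 2
        )
    if measured_mg_per_kg is not None:
        report["retention_pulmonary_percent"] = round(
            retention_percent(
                measured_mg_per_kg, report["pulmonary_dose_mg_per_kg"]
            )
        )
    return report
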