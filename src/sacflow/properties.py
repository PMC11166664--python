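"""Effective thermophysical properties of a two-species (hybrid) nanofluid.

The carrier is whole blood, treated as a Newtonian liquid with constant
properties; the dispersed phases are gold (species 1) and silver (species 2)
nanoparticles at small volume fractions ``phi1``, ``phi2``.  Bulk mixture
properties follow the classical dilute-suspension closures applied in two
steps — first species 1 in the carrier, then species 2 in that intermediate
nanofluid:

* density and volumetric heat capacity: volume-weighted mixing,
* dynamic viscosity: Brinkman, ``mu_f / ((1-phi1)^2.5 (1-phi2)^2.5)``,
* thermal conductivity: Maxwell (spheres), applied sequentially.

The species order (gold first, silver second) matters for the two-step
Maxwell/Brinkman laws and is fixed by convention here; callers may pass the
species in any order they choose but the laws are not symmetric under swap.

All properties are temperature independent.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "MaterialRecord",
    "Loading",
    "EffectiveProperties",
    "material_table",
    "effective_density",
    "effective_heat_capacity",
    "effective_viscosity",
    "effective_conductivity",
    "effective_bundle",
]

#: Handbook specific heat of silver, J kg^-1 K^-1, selectable via
#: ``material_table(corrected_silver_cp=True)``.  The bundled table ships the
#: value as printed in the source data (2354), roughly ten times larger.
SILVER_CP_HANDBOOK = 235.0


@dataclass(frozen=True)
class MaterialRecord:
    """Constant thermophysical properties of one material.

    Units: cp J kg^-1 K^-1, k W m^-1 K^-1, mu Pa s, rho kg m^-3.
    """

    name: str
    cp: float
    k: float
    mu: float
    rho: float

    def __post_init__(self) -> None:
        for field in ("cp", "k", "mu", "rho"):
            v = getattr(self, field)
            if not (v > 0.0):
                raise ValueError(f"{self.name}: {field} must be positive, got {v}")

    @property
    def rho_cp(self) -> float:
        """Volumetric heat capacity rho*cp, J m^-3 K^-1."""
        return self.rho * self.cp


@dataclass(frozen=True)
class Loading:
    """Particle volume fractions: ``phi1`` gold, ``phi2`` silver."""

    phi1: float = 0.0
    phi2: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("phi1", self.phi1), ("phi2", self.phi2)):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.phi1 + self.phi2 >= 0.5:
            raise ValueError(
                "total volume fraction must stay below 0.5 "
                f"(dilute-suspension closures), got {self.phi1 + self.phi2}"
            )


@dataclass(frozen=True)
class EffectiveProperties:
    """Bundle of effective mixture scalars (SI units)."""

    rho: float
    rho_cp: float
    mu: float
    k: float
    nu: float
    alpha: float

    def __post_init__(self) -> None:
        for field in ("rho", "rho_cp", "mu", "k", "nu", "alpha"):
            if not (getattr(self, field) > 0.0):
                raise ValueError(f"{field} must be positive")

    @property
    def cp(self) -> float:
        """Effective specific heat, J kg^-1 K^-1."""
        return self.rho_cp / self.rho


def material_table(path=None, corrected_silver_cp: bool = False) -> dict[str, MaterialRecord]:
    """Load a material table (bundled blood/gold/silver constants by default).

    Parameters
    ----------
    path
        Optional CSV with columns ``name, cp, k, mu, rho`` replacing the
        bundled table.
    corrected_silver_cp
        Replace the bundled silver specific heat by the handbook value
        (~235 J kg^-1 K^-1); only meaningful for the bundled table.
    """
    if path is None:
        text = resources.files("sacflow.data").joinpath("materials.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    records = {}
    for row in rows:
        rec = MaterialRecord(
            name=row["name"],
            cp=float(row["cp"]),
            k=float(row["k"]),
            mu=float(row["mu"]),
            rho=float(row["rho"]),
        )
        records[rec.name] = rec
    if corrected_silver_cp and "silver" in records:
        s = records["silver"]
        records["silver"] = MaterialRecord("silver", SILVER_CP_HANDBOOK, s.k, s.mu, s.rho)
    return records


def effective_density(
    base: MaterialRecord, s1: MaterialRecord, s2: MaterialRecord, load: Loading
) -> float:
    """Two-step volume-weighted mixture density, kg m^-3."""
    p1, p2 = load.phi1, load.phi2
    return (1.0 - p2) * ((1.0 - p1) * base.rho + p1 * s1.rho) + p2 * s2.rho


def effective_heat_capacity(
    base: MaterialRecord, s1: MaterialRecord, s2: MaterialRecord, load: Loading
) -> float:
    """Two-step volume-weighted volumetric heat capacity (rho*cp), J m^-3 K^-1."""
    p1, p2 = load.phi1, load.phi2
    return (1.0 - p2) * ((1.0 - p1) * base.rho_cp + p1 * s1.rho_cp) + p2 * s2.rho_cp


def effective_viscosity(base: MaterialRecord, load: Loading) -> float:
    """Two-step Brinkman dynamic viscosity, Pa s."""
    return base.mu / ((1.0 - load.phi1) ** 2.5 * (1.0 - load.phi2) ** 2.5)


def _maxwell(k_fluid: float, k_solid: float, phi: float) -> float:
    """Maxwell effective conductivity of spheres at volume fraction phi."""
    num = k_solid + 2.0 * k_fluid - 2.0 * phi * (k_fluid - k_solid)
    den = k_solid + 2.0 * k_fluid + phi * (k_fluid - k_solid)
    return num / den * k_fluid


def effective_conductivity(
    base: MaterialRecord, s1: MaterialRecord, s2: MaterialRecord, load: Loading
) -> float:
    """Two-step Maxwell thermal conductivity, W m^-1 K^-1.

    Species 1 is homogenized into the carrier first; species 2 is then
    homogenized into that intermediate nanofluid.
    """
    if base.k <= 0 or s1.k <= 0 or s2.k <= 0:
        raise ValueError("conductivities must be positive")
    k_nf = _maxwell(base.k, s1.k, load.phi1)
    return _maxwell(k_nf, s2.k, load.phi2)


def effective_bundle(
    base: MaterialRecord, s1: MaterialRecord, s2: MaterialRecord, load: Loading
) -> EffectiveProperties:
    """All effective scalars plus the derived kinematic viscosity and
    thermal diffusivity."""
    rho = effective_density(base, s1, s2, load)
    rho_cp = effective_heat_capacity(base, s1, s2, load)
    mu = effective_viscosity(base, load)
    k = effective_conductivity(base, s1, s2, load)
    return EffectiveProperties(rho=rho, rho_cp=rho_cp, mu=mu, k=k, nu=mu / rho, alpha=k / rho_cp)
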