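"""Material properties for the electro-thermal model.

Every voxel label carries an electrical conductivity sigma (S/m), thermal
conductivity k (W/m/K), mass density rho (kg/m^3), specific heat c (J/kg/K),
blood perfusion rate omega (1/s) and metabolic heat Q (W/kg).  The table also
holds the blood constants of the Pennes perfusion sink rho_b*c_b*omega*(T-Tb).

The liquid-metal electrode values (sigma = 3.4e6 S/m, k = 9.8 W/m/K) are the
published properties of the gallium-indium eutectic used as the conformable
bronchial electrode; the saline / gold-nanoparticle fluid conductivities
(0.113 and 0.138 S/m) are the published values for those infusates.  Tissue
values are literature-style defaults for inflated lung, skeletal muscle and a
muscle-like tumor surrogate at ~500 kHz; they are configuration, not physics
constants, and every experiment logs the table it ran with.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "Label",
    "SigmaModel",
    "MaterialRecord",
    "MaterialTable",
    "default_table",
    "sigma_of_temperature",
    "NACL_SIGMA",
    "AUNP_SIGMA",
    "SIGMA_FLOOR",
]

#: Conductivity floor assigned to airway air.  Air is effectively an insulator
#: at 480 kHz; a small positive floor keeps the finite-volume operator an
#: M-matrix without opening a conductive path.
SIGMA_FLOOR = 1.0e-5

NACL_SIGMA = 0.113   # hypertonic saline, S/m
AUNP_SIGMA = 0.138   # gold-nanoparticle suspension, S/m


class Label(enum.IntEnum):
    """Voxel tissue/material labels."""

    PARENCHYMA = 1
    AIRWAY_AIR = 2
    ELECTRODE = 3
    CONDUCTIVE_FLUID = 4
    TUMOR = 5
    MUSCLE = 6
    NON_TARGET_ORGAN = 7


class SigmaModel(enum.Enum):
    """Temperature dependence of the electrical conductivity."""

    CONSTANT = "constant"
    LINEAR_ROLLOFF = "linear_rolloff"


@dataclass(frozen=True)
class MaterialRecord:
    """Per-label material properties (SI units; see module docstring)."""

    sigma: float          # electrical conductivity, S/m
    k: float              # thermal conductivity, W/m/K
    rho: float            # mass density, kg/m^3
    c: float              # specific heat, J/kg/K
    omega: float = 0.0    # blood perfusion rate, 1/s
    q_met: float = 0.0    # metabolic heat, W/kg
    note: str = ""        # provenance of the default values

    def validate(self) -> None:
        if not self.sigma >= SIGMA_FLOOR:
            raise ConfigurationError(
                f"sigma={self.sigma} below the conductivity floor {SIGMA_FLOOR}")
        if self.k <= 0 or self.rho <= 0 or self.c <= 0:
            raise ConfigurationError("k, rho and c must all be positive")
        if self.omega < 0 or self.q_met < 0:
            raise ConfigurationError("omega and Q must be non-negative")


@dataclass
class MaterialTable:
    """Complete property table for every voxel label plus blood constants."""

    records: dict[Label, MaterialRecord]
    rho_b: float = 1050.0    # blood density, kg/m^3
    c_b: float = 3617.0      # blood specific heat, J/kg/K
    T_b: float = 37.0        # blood / body-core temperature, degC

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for label in Label:
            if label not in self.records:
                raise ConfigurationError(f"material table missing label {label.name}")
            self.records[label].validate()
        if self.rho_b <= 0 or self.c_b <= 0:
            raise ConfigurationError("blood density and specific heat must be positive")
        if not 30.0 <= self.T_b <= 45.0:
            raise ConfigurationError(f"T_b={self.T_b} outside the physiologic 30-45 degC band")

    def __getitem__(self, label: Label) -> MaterialRecord:
        return self.records[Label(label)]

    # -- grid lookups ------------------------------------------------------

    def _lut(self, attr: str) -> np.ndarray:
        lut = np.zeros(max(Label) + 1)
        for label, rec in self.records.items():
            lut[int(label)] = getattr(rec, attr)
        return lut

    def property_grid(self, labels: np.ndarray, attr: str) -> np.ndarray:
        """Map a label grid to the per-voxel value of one property."""
        return self._lut(attr)[labels]

    def sigma_grid(self, labels: np.ndarray) -> np.ndarray:
        return self.property_grid(labels, "sigma")

    def perfusion_grid(self, labels: np.ndarray) -> np.ndarray:
        """Volumetric perfusion coefficient rho_b*c_b*omega, W/m^3/K."""
        return self.rho_b * self.c_b * self.property_grid(labels, "omega")

    # -- variants ----------------------------------------------------------

    def with_override(self, label: Label, **kwargs) -> "MaterialTable":
        """Return a copy with one label's record partially replaced."""
        records = dict(self.records)
        records[Label(label)] = replace(records[Label(label)], **kwargs)
        return MaterialTable(records, rho_b=self.rho_b, c_b=self.c_b, T_b=self.T_b)

    def with_fluid(self, kind: str) -> "MaterialTable":
        """Select the conductive-fluid variant ('nacl' or 'aunp')."""
        sigma = {"nacl": NACL_SIGMA, "aunp": AUNP_SIGMA}.get(kind.lower())
        if sigma is None:
            raise ConfigurationError(f"unknown conductive fluid {kind!r}")
        return self.with_override(Label.CONDUCTIVE_FLUID, sigma=sigma,
                                  note=f"{kind} infusate")

    def without_perfusion(self) -> "MaterialTable":
        """Ex-vivo variant: omega = 0 for every label."""
        table = self
        for label in Label:
            if table.records[label].omega:
                table = table.with_override(label, omega=0.0)
        return table

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "blood": {"rho_b": self.rho_b, "c_b": self.c_b, "T_b": self.T_b},
            "labels": {
                label.name: {
                    "sigma": rec.sigma, "k": rec.k, "rho": rec.rho, "c": rec.c,
                    "omega": rec.omega, "q_met": rec.q_met, "note": rec.note,
                }
                for label, rec in self.records.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialTable":
        blood = data.get("blood", {})
        records = {
            Label[name]: MaterialRecord(**rec)
            for name, rec in data["labels"].items()
        }
        return cls(records, **blood)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MaterialTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_table() -> MaterialTable:
    """Documented default property table (see module docstring)."""
    records = {
        Label.PARENCHYMA: MaterialRecord(
            sigma=0.10, k=0.39, rho=394.0, c=3886.0, omega=0.001,
            note="inflated lung, literature-style defaults at ~500 kHz"),
        Label.AIRWAY_AIR: MaterialRecord(
            sigma=SIGMA_FLOOR, k=0.03, rho=1.2, c=1005.0,
            note="lumen air; sigma is the documented floor, not physical air"),
        Label.ELECTRODE: MaterialRecord(
            sigma=3.4e6, k=9.8, rho=6250.0, c=404.0,
            note="gallium-indium eutectic: published sigma and k; rho, c defaults"),
        Label.CONDUCTIVE_FLUID: MaterialRecord(
            sigma=NACL_SIGMA, k=0.60, rho=1000.0, c=4180.0,
            note="hypertonic saline infusate; published sigma, water-like thermals"),
        Label.TUMOR: MaterialRecord(
            sigma=0.45, k=0.52, rho=1079.0, c=3540.0, omega=0.0009,
            note="muscle-like tumor surrogate"),
        Label.MUSCLE: MaterialRecord(
            sigma=0.45, k=0.49, rho=1090.0, c=3421.0, omega=0.0007,
            note="skeletal muscle (chest-wall analogue)"),
        Label.NON_TARGET_ORGAN: MaterialRecord(
            sigma=0.45, k=0.49, rho=1090.0, c=3421.0, omega=0.0007,
            note="muscle-like non-target organ surrogate"),
    }
    return MaterialTable(records)


def sigma_of_temperature(sigma0, T, model: SigmaModel = SigmaModel.CONSTANT):
    """Temperature-dependent electrical conductivity.

    CONSTANT returns ``sigma0`` unchanged.  LINEAR_ROLLOFF increases sigma by
    1.5 %/degC above body temperature (ionic mobility) and collapses it to 1 %
    of baseline at and above 99 degC, a simple surrogate for tissue
    desiccation; this collapse is what drives the generator's impedance
    cut-off.  Scalar or array inputs are accepted.
    """
    model = SigmaModel(model)
    if model is SigmaModel.CONSTANT:
        return sigma0 if np.isscalar(T) else np.broadcast_to(
            np.asarray(sigma0, dtype=float), np.shape(T)).copy()
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ConfigurationError("temperature grid contains non-finite values")
    sigma0 = np.asarray(sigma0, dtype=float)
    out = sigma0 * (1.0 + 0.015 * (T - 37.0))
    out = np.where(T >= 99.0, sigma0 * 0.01, out)
    if out.ndim == 0:
        return float(out)
    return out
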