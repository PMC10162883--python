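"""Phantom-based HU-to-density calibration.

A tissue-characterization phantom scanned alongside the specimen provides
inserts of known hydroxyapatite-equivalent density; an ordinary
least-squares line through (measured HU, nominal density) converts any HU
value to volumetric bone-equivalent density (mg/cm3 by convention — the
``unit`` field records the actual unit rather than guessing conversions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateCalibrationError, ParameterError


@dataclass(frozen=True)
class PhantomInsert:
    """One calibration rod: nominal density and its measured mean HU."""

    nominal_density: float
    measured_hu: float

    def __post_init__(self):
        if self.nominal_density < 0:
            raise ParameterError("nominal density must be >= 0")


@dataclass(frozen=True)
class PhantomCalibration:
    """Linear HU -> density map fitted to phantom inserts."""

    slope: float
    intercept: float
    r_squared: float
    n_inserts: int
    unit: str = "mg/cm3"

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope == 0:
            raise DegenerateCalibrationError("calibration slope must be finite and nonzero")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "n_inserts": self.n_inserts,
                    "unit": self.unit,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomCalibration":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            slope=float(obj["slope"]),
            intercept=float(obj["intercept"]),
            r_squared=float(obj.get("r_squared", float("nan"))),
            n_inserts=int(obj.get("n_inserts", 0)),
            unit=obj.get("unit", "mg/cm3"),
        )


def load_inserts(path: str | Path) -> list[PhantomInsert]:
    """Read inserts from JSON: ``{"inserts": [{"density": x, "hu": y}, ...]}``."""
    with open(path) as fh:
        obj = json.load(fh)
    return [PhantomInsert(float(e["density"]), float(e["hu"])) for e in obj["inserts"]]


def fit_calibration(inserts: list[PhantomInsert], unit: str = "mg/cm3") -> PhantomCalibration:
    """Ordinary least squares of nominal density on measured HU.

    Requires at least two inserts with distinct HU values.
    """
    if len(inserts) < 2:
        raise DegenerateCalibrationError("need at least 2 phantom inserts")
    hu = np.array([i.measured_hu for i in inserts], dtype=float)
    dens = np.array([i.nominal_density for i in inserts], dtype=float)
    if np.ptp(hu) == 0:
        raise DegenerateCalibrationError("all inserts have identical HU; cannot fit a line")
    slope, intercept = np.polyfit(hu, dens, 1)
    pred = slope * hu + intercept
    ss_res = float(np.sum((dens - pred) ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PhantomCalibration(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(1.0, r_squared)),
        n_inserts=len(inserts),
        unit=unit,
    )


def hu_to_bmd(hu, cal: PhantomCalibration):
    """Apply the calibration line element-wise: ``density = slope * HU + intercept``."""
    hu = np.asarray(hu, dtype=float)
    out = cal.slope * hu + cal.intercept
    return float(out) if out.ndim == 0 else out
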