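"""Yield-to-concentration calibration for PIGE (F), PIXE (Ca) and µCT.

PIGE gamma yield and PIXE X-ray yield are first-order proportional to the
emitting element's concentration, and µCT grey value is affine in mineral
density over the phantom range, so the default calibration is a least-squares
line ``yield = slope·concentration + intercept`` (µCT:
``grey = slope·density + intercept``).  A quadratic option exists behind the
``degree`` flag for curvature checks but is off by default.

Fluoridated-apatite references Ca₁₀(PO₄)₆(OH)₂₋₂ₓF₂ₓ are specified by their
fluoridation fraction x; :func:`reference_f_content` converts x to a
stoichiometric F mass fraction from standard atomic weights (x = 1,
fluorapatite, ≈ 3.767 wt% F).

Calibrated concentrations below zero are floored at 0: counts below the
fitted background cannot mean negative concentration.  The floor slightly
biases near-zero F values upward, which matters for F-uptake integrals over
long background stretches and is therefore documented here and in the
methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDesignError, InputError
from .profiles import DepthProfile, LineScan

#: Standard atomic weights (IUPAC 2021, conventional values), g/mol.
ATOMIC_MASS = {
    "Ca": 40.078,
    "P": 30.973761998,
    "O": 15.999,
    "H": 1.008,
    "F": 18.998403163,
}

#: curve kind -> (LineScan channel, concentration unit)
CURVE_KINDS = {
    "pige_f": ("f", "ppm"),
    "pixe_ca": ("ca", "wt%"),
    "uct_density": (None, "mg/cm3"),
}


def reference_f_content(x: float, unit: str = "wt%") -> float:
    """Stoichiometric F content of Ca₁₀(PO₄)₆(OH)₂₋₂ₓF₂ₓ.

    Parameters
    ----------
    x : fluoridation fraction in [0, 1] (0 = hydroxyapatite, 1 = fluorapatite).
    unit : ``"wt%"`` (default) or ``"ppm"``.

    Strictly increasing in x; x = 1 gives the fluorapatite value ≈ 3.767 wt%.
    """
    if not (0.0 <= x <= 1.0):
        raise InputError(f"fluoridation fraction x must lie in [0, 1], got {x}")
    m = ATOMIC_MASS
    formula_mass = (
        10 * m["Ca"]
        + 6 * (m["P"] + 4 * m["O"])
        + (2 - 2 * x) * (m["O"] + m["H"])
        + 2 * x * m["F"]
    )
    wt = 100.0 * (2 * x * m["F"]) / formula_mass
    if unit == "wt%":
        return wt
    if unit == "ppm":
        return wt * 1.0e4
    raise InputError(f"unknown unit {unit!r}; expected 'wt%' or 'ppm'")


@dataclass(frozen=True)
class ReferenceMaterial:
    """One calibration reference: a known concentration with its measured
    yield (counts per unit charge).

    Specify either the fluoridation fraction ``x`` of an apatite reference
    (concentration derived stoichiometrically) or a direct ``concentration``
    with its ``unit``.
    """

    label: str
    measured_yield: float
    x: float | None = None
    concentration: float | None = None
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if (self.x is None) == (self.concentration is None):
            raise InputError(
                f"reference {self.label!r}: give exactly one of x or concentration"
            )
        if self.measured_yield < 0:
            raise InputError(f"reference {self.label!r}: negative measured yield")
        if self.x is not None and not (0.0 <= self.x <= 1.0):
            raise InputError(f"reference {self.label!r}: x outside [0, 1]")

    def concentration_in(self, unit: str) -> float:
        if self.x is not None:
            return reference_f_content(self.x, unit)
        if self.unit == unit:
            return float(self.concentration)
        conv = {("wt%", "ppm"): 1e4, ("ppm", "wt%"): 1e-4}
        try:
            return float(self.concentration) * conv[(self.unit, unit)]
        except KeyError:
            raise InputError(f"cannot convert {self.unit!r} to {unit!r}")


@dataclass(frozen=True)
class UctPhantomSet:
    """Density phantoms for µCT: (density mg/cm³, mean grey value) pairs,
    e.g. hydroxyapatite disks at 100–400 mg/cm³ plus an aluminum pole."""

    phantoms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.phantoms) < 2:
            raise InputError("need at least two phantoms")
        dens = [d for d, _ in self.phantoms]
        if any(d <= 0 for d in dens):
            raise InputError("phantom densities must be positive")
        if len(set(dens)) < 2:
            raise DegenerateDesignError("phantom densities must include >= 2 levels")


@dataclass
class CalibrationCurve:
    """Fitted map between yield (or grey value) and concentration (density).

    Forward model: ``yield = quad·c² + slope·c + intercept`` (quad = 0 for
    the default linear fit).  ``unit`` is the concentration unit of the
    abscissa the curve was fitted on.
    """

    kind: str
    slope: float
    intercept: float
    r_squared: float
    unit: str
    quad: float = 0.0
    references_used: list[str] = field(default_factory=list)

    def concentration(self, yield_per_charge: np.ndarray) -> np.ndarray:
        """Invert the forward model (positive branch for quadratic fits)."""
        y = np.asarray(yield_per_charge, dtype=float)
        if self.quad == 0.0:
            return (y - self.intercept) / self.slope
        disc = self.slope**2 - 4.0 * self.quad * (self.intercept - y)
        return (-self.slope + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * self.quad)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "unit": self.unit,
            "quad": self.quad,
            "references_used": list(self.references_used),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_calibration(
    references: Iterable[ReferenceMaterial] | UctPhantomSet,
    kind: str,
    degree: int = 1,
    unit: str | None = None,
) -> CalibrationCurve:
    """Least-squares calibration fit.

    For ``pige_f``/``pixe_ca``: yield (counts per unit charge) against
    concentration (ppm F / wt% Ca by default; ``unit`` overrides the
    abscissa unit, e.g. ``"wt%"`` for a PIGE curve in weight percent).  For
    ``uct_density``: grey value against density (mg/cm³).  Requires at least
    degree+1 references with distinct concentrations; an all-identical
    design raises :class:`DegenerateDesignError`.  The fit is invariant to
    reference order.
    """
    if kind not in CURVE_KINDS:
        raise InputError(f"unknown calibration kind {kind!r}")
    if degree not in (1, 2):
        raise InputError("degree must be 1 (linear) or 2 (quadratic)")
    if unit is None:
        unit = CURVE_KINDS[kind][1]
    if isinstance(references, UctPhantomSet):
        conc = np.array([d for d, _ in references.phantoms], dtype=float)
        yld = np.array([g for _, g in references.phantoms], dtype=float)
        labels = [f"phantom_{d:g}" for d in conc]
    else:
        refs = list(references)
        if not refs:
            raise InputError("no references given")
        conc = np.array([r.concentration_in(unit) for r in refs])
        yld = np.array([r.measured_yield for r in refs], dtype=float)
        labels = [r.label for r in refs]
    if np.unique(conc).size < degree + 1:
        raise DegenerateDesignError(
            f"need >= {degree + 1} distinct concentrations, got {np.unique(conc).size}"
        )
    coeffs = np.polynomial.polynomial.polyfit(conc, yld, degree)
    fitted = np.polynomial.polynomial.polyval(conc, coeffs)
    ss_res = float(np.sum((yld - fitted) ** 2))
    ss_tot = float(np.sum((yld - np.mean(yld)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    quad = float(coeffs[2]) if degree == 2 else 0.0
    return CalibrationCurve(
        kind=kind,
        slope=float(coeffs[1]),
        intercept=float(coeffs[0]),
        r_squared=min(1.0, r2),
        unit=unit,
        quad=quad,
        references_used=labels,
    )


def apply_calibration(
    scan: LineScan,
    curve: CalibrationCurve,
    channel: str,
    floor_negative: bool = True,
) -> DepthProfile:
    """Convert one raw channel of a line scan to a concentration profile.

    concentration_i = ((counts_i / charge_i) − intercept) / slope, with
    negative results floored at 0 unless ``floor_negative=False``.  The
    curve's kind must match the channel; non-positive charge raises an error
    naming the offending position.
    """
    expected = CURVE_KINDS.get(curve.kind, (None,))[0]
    if expected != channel:
        raise InputError(
            f"curve kind {curve.kind!r} does not calibrate channel {channel!r}"
        )
    bad = np.flatnonzero(scan.charge <= 0)
    if bad.size:
        raise InputError(
            f"non-positive charge at position {scan.position_um[bad[0]]:g} um"
        )
    conc = curve.concentration(scan.counts(channel) / scan.charge)
    if floor_negative:
        conc = np.maximum(conc, 0.0)
    quantity = {"f": "f", "ca": "ca"}[channel]
    return DepthProfile(scan.position_um.copy(), conc, quantity=quantity,
                        unit=curve.unit)


def apply_uct_calibration(
    grey_profile: DepthProfile,
    curve: CalibrationCurve,
    floor_negative: bool = True,
) -> DepthProfile:
    """Convert a µCT grey-value profile to mineral density (mg/cm³)."""
    if curve.kind != "uct_density":
        raise InputError(f"curve kind {curve.kind!r} is not a uCT density curve")
    dens = curve.concentration(grey_profile.values)
    if floor_negative:
        dens = np.maximum(dens, 0.0)
    return DepthProfile(
        grey_profile.position_um.copy(), dens, quantity="mineral_density",
        unit=curve.unit, missing=grey_profile.missing.copy(),
    )


def f_lod_from_background(
    background_counts: float, curve: CalibrationCurve, charge: float = 1.0
) -> float:
    """Detection limit in concentration units: the calibrated equivalent of
    ``background + 3·sqrt(background)`` counts.

    With an intercept that absorbs the background, this reduces to
    3·sqrt(background)/(slope·charge).
    """
    if background_counts < 0:
        raise InputError("background_counts must be non-negative")
    thresh = (background_counts + 3.0 * np.sqrt(background_counts)) / charge
    return float(max(0.0, curve.concentration(np.array([thresh]))[0]))
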