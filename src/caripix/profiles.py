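"""In-memory containers: raw line scans and calibrated depth profiles.

A :class:`LineScan` is the instrument-facing record of one PIXE/PIGE line
analysis: per-position raw channel counts (Ca Kα X-rays, F gamma rays from
the ¹⁹F(p,αγ)¹⁶O reaction, Cu Kα from the fiducial foil) plus the accumulated
beam charge at each point.  A :class:`DepthProfile` is one calibrated
quantity (wt% Ca, ppm F, mg/cm³ mineral density, or raw µCT grey value)
against depth in µm, with an explicit missing-data mask so that registration
never has to extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LINESCAN_COLUMNS = ("position_um", "counts_ca", "counts_f", "counts_cu", "charge")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class LineScan:
    """Raw counts per scan position for the three detector channels.

    Positions are stage coordinates in µm and must be strictly increasing;
    ``charge`` is the accumulated beam charge at each point (arbitrary but
    consistent units), used to normalise yields before calibration.
    """

    position_um: np.ndarray
    counts_ca: np.ndarray
    counts_f: np.ndarray
    counts_cu: np.ndarray
    charge: np.ndarray

    def __post_init__(self) -> None:
        self.position_um = _as_float_array(self.position_um, "position_um")
        n = self.position_um.size
        for name in ("counts_ca", "counts_f", "counts_cu", "charge"):
            arr = _as_float_array(getattr(self, name), name)
            if arr.size != n:
                raise ValueError(
                    f"{name} has {arr.size} entries, expected {n} to match position_um"
                )
            setattr(self, name, arr)
        if n == 0:
            raise ValueError("empty line scan")
        if n > 1 and not np.all(np.diff(self.position_um) > 0):
            bad = int(np.flatnonzero(np.diff(self.position_um) <= 0)[0]) + 1
            raise ValueError(
                f"positions must be strictly increasing (violated at index {bad})"
            )

    @property
    def step(self) -> float:
        """Median spacing between scan points (µm)."""
        if self.position_um.size < 2:
            return float("nan")
        return float(np.median(np.diff(self.position_um)))

    def counts(self, channel: str) -> np.ndarray:
        try:
            return getattr(self, f"counts_{channel}")
        except AttributeError:
            raise KeyError(f"unknown channel {channel!r}; expected 'ca', 'f' or 'cu'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_um": self.position_um,
                "counts_ca": self.counts_ca,
                "counts_f": self.counts_f,
                "counts_cu": self.counts_cu,
                "charge": self.charge,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LineScan":
        return cls(*(df[c].to_numpy(dtype=float) for c in LINESCAN_COLUMNS))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineScan):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in LINESCAN_COLUMNS
        )


@dataclass
class DepthProfile:
    """One calibrated quantity against depth.

    ``missing`` flags positions where the value is not defined (e.g. outside
    the overlap of two registered scans); flagged values are NaN-like and are
    skipped by every downstream computation.
    """

    position_um: np.ndarray
    values: np.ndarray
    quantity: str = ""
    unit: str = ""
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.position_um = _as_float_array(self.position_um, "position_um")
        self.values = _as_float_array(self.values, "values")
        if self.values.size != self.position_um.size:
            raise ValueError("values and position_um lengths differ")
        if self.missing is None:
            self.missing = np.zeros(self.position_um.size, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.size != self.position_um.size:
                raise ValueError("missing mask length differs from positions")

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (positions, values) with missing points dropped."""
        keep = ~self.missing
        return self.position_um[keep], self.values[keep]

    def shifted(self, dz: float) -> "DepthProfile":
        """Rigidly translate the depth axis by ``dz`` µm."""
        return replace(self, position_um=self.position_um + dz)

    def interpolated_to(self, grid: np.ndarray) -> "DepthProfile":
        """Linearly interpolate onto ``grid``; points outside coverage are
        flagged missing, never extrapolated."""
        grid = _as_float_array(np.asarray(grid), "grid")
        pos, val = self.valid()
        if pos.size == 0:
            return DepthProfile(
                grid, np.zeros_like(grid), self.quantity, self.unit,
                np.ones(grid.size, dtype=bool),
            )
        out = np.interp(grid, pos, val)
        missing = (grid < pos[0]) | (grid > pos[-1])
        return DepthProfile(grid, out, self.quantity, self.unit, missing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthProfile):
            return NotImplemented
        return (
            self.quantity == other.quantity
            and self.unit == other.unit
            and np.array_equal(self.position_um, other.position_um)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.missing, other.missing)
        )
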