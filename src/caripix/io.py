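"""Text-format I/O: line scans, aligned profiles, references and configs.

All on-disk formats are human-inspectable text: TSV for scans and profiles,
JSON for structured results.  A line scan is a TSV with the exact header
``position_um  counts_ca  counts_f  counts_cu  charge`` and strictly
increasing positions; malformed rows are reported with 1-based file line
numbers (the header is line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ReferenceMaterial, UctPhantomSet
from .errors import InputError
from .profiles import LINESCAN_COLUMNS, DepthProfile, LineScan
from .registration import SequentialPair


def read_linescan(path) -> LineScan:
    """Read a line-scan TSV, validating columns, numeric cells and strictly
    increasing positions.  Errors name the offending file line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty input file")
    missing = [c for c in LINESCAN_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns: {', '.join(missing)}")
    extra = [c for c in df.columns if c not in LINESCAN_COLUMNS]
    if extra:
        raise InputError(f"{path}: unexpected columns: {', '.join(extra)}")
    if len(df) == 0:
        raise InputError(f"{path}: no data rows")
    for col in LINESCAN_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise InputError(f"{path}: non-numeric value in column {col!r} "
                             f"at line {line}")
        df[col] = converted
    pos = df["position_um"].to_numpy(dtype=float)
    if pos.size > 1:
        diffs = np.diff(pos)
        if np.any(diffs <= 0):
            line = int(np.flatnonzero(diffs <= 0)[0]) + 3
            raise InputError(
                f"{path}: positions not strictly increasing at line {line}"
            )
    return LineScan.from_frame(df)


def write_linescan(scan: LineScan, path) -> None:
    """Write a line scan as TSV; read_linescan round-trips it losslessly."""
    scan.to_frame().to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: DepthProfile, path) -> None:
    pd.DataFrame({
        "position_um": profile.position_um,
        "value": profile.values,
        "missing": profile.missing.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, quantity: str = "", unit: str = "") -> DepthProfile:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("position_um", "value"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    missing = df["missing"].to_numpy(dtype=bool) if "missing" in df.columns else None
    return DepthProfile(
        df["position_um"].to_numpy(dtype=float),
        df["value"].to_numpy(dtype=float),
        quantity=quantity, unit=unit, missing=missing,
    )


def write_aligned_pair(pair: SequentialPair, path) -> None:
    """Write a registered before/after profile set as one TSV
    (position_um, <element>_before, <element>_after, <element>_missing)."""
    cols: dict[str, np.ndarray] = {"position_um": pair.grid}
    for element, (before, after) in pair.profiles.items():
        cols[f"{element}_before"] = before.values
        cols[f"{element}_after"] = after.values
        cols[f"{element}_missing"] = (before.missing | after.missing).astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def registration_report(pair: SequentialPair) -> dict:
    def _fix(f):
        return None if f is None else {
            "position_um": f.position, "peak_counts": f.peak_counts, "snr": f.snr
        }
    return {
        "applied_shift_um": pair.applied_shift,
        "fiducial_position_um": pair.fiducial_position,
        "fiducial_before": _fix(pair.fiducial_before),
        "fiducial_after": _fix(pair.fiducial_after),
    }


def read_references(path, kind: str) -> list[ReferenceMaterial] | UctPhantomSet:
    """Read a calibration reference TSV with columns
    (label, x_or_density, yield_or_grey).

    For ``pige_f`` the second column is the apatite fluoridation fraction x;
    for ``pixe_ca`` it is a direct concentration in wt%; for ``uct_density``
    a density in mg/cm³ (returning a phantom set).
    """
    df = pd.read_csv(path, sep="\t")
    need = ("label", "x_or_density", "yield_or_grey")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns: {', '.join(missing)}")
    if kind == "uct_density":
        return UctPhantomSet(tuple(
            (float(r.x_or_density), float(r.yield_or_grey))
            for r in df.itertuples()
        ))
    refs = []
    for r in df.itertuples():
        if kind == "pige_f":
            refs.append(ReferenceMaterial(
                label=str(r.label), x=float(r.x_or_density),
                measured_yield=float(r.yield_or_grey),
            ))
        elif kind == "pixe_ca":
            refs.append(ReferenceMaterial(
                label=str(r.label), concentration=float(r.x_or_density),
                unit="wt%", measured_yield=float(r.yield_or_grey),
            ))
        else:
            raise InputError(f"unknown calibration kind {kind!r}")
    return refs


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
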