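"""Lesion boundaries and integral demineralization metrics.

All metrics work on profiles binned at 10 µm intervals anchored at the Cu
reference point, mirroring the analysis protocol: average concentrations are
computed per 10 µm bin from the outermost surface to the Cu reference, then

* **Ca loss** (wt%·µm) integrates the before-minus-after Ca difference,
* **F uptake** (ppmF·µm) cumulates the binned F concentration,
* **F penetration** (µm) is the distance from the outermost surface to the
  first bin with F below the detection limit,
* **mineral loss** (mg/cm³·µm) is the µCT analog of Ca loss.

The outermost surface of a lesion is the position containing 5% of the mean
Ca of intact dentin, the innermost surface the position containing 95%, both
found by linear interpolation scanning inward.  Intact dentin is averaged
over a fixed-width window adjacent to the Cu reference on the sound side.
Losses integrate from the BEFORE profile's outermost surface so that eroded
material counts as loss.  Rectangle-rule integration on the bins matches the
"average per 10 µm interval, then integrate" protocol; negative bin
differences are kept by default (unbiased under noise) with an optional
non-negativity clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import CalibrationCurve, apply_calibration, f_lod_from_background
from .errors import InputError, InsufficientOverlapError
from .profiles import DepthProfile, LineScan
from .registration import SequentialPair, superimpose


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the lesion analysis.

    ``outer_frac``/``inner_frac`` are the 5%/95% boundary thresholds on the
    intact-dentin Ca mean; ``f_lod`` (concentration units) overrides the
    background-derived F detection limit; ``intact_window`` is the width of
    the intact-dentin averaging region adjacent to the Cu reference.
    """

    bin_width: float = 10.0
    outer_frac: float = 0.05
    inner_frac: float = 0.95
    f_lod: float | None = None
    intact_window: float = 200.0
    clamp_nonnegative: bool = False
    integration: str = "rectangle"   # or "trapezoid"
    uct_region_um: float = 800.0
    f_region: str = "before_surface"  # or "own_surface"

    def __post_init__(self) -> None:
        if not (0.0 < self.outer_frac < self.inner_frac < 1.0):
            raise InputError("require 0 < outer_frac < inner_frac < 1")
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")
        if self.intact_window <= 0:
            raise InputError("intact_window must be positive")
        if self.integration not in ("rectangle", "trapezoid"):
            raise InputError("integration must be 'rectangle' or 'trapezoid'")
        if self.f_region not in ("before_surface", "own_surface"):
            raise InputError("f_region must be 'before_surface' or 'own_surface'")


@dataclass
class BinnedProfile:
    """Profile averaged in fixed-width bins anchored at the Cu reference.

    ``lower_edges`` are ascending bin lower edges; the topmost bin ends at
    the reference position.  Bins that cover no data points are flagged
    missing.
    """

    lower_edges: np.ndarray
    width: float
    values: np.ndarray
    missing: np.ndarray
    quantity: str = ""
    unit: str = ""

    @property
    def centers(self) -> np.ndarray:
        return self.lower_edges + 0.5 * self.width

    @property
    def reference(self) -> float:
        return float(self.lower_edges[-1] + self.width)


@dataclass(frozen=True)
class LesionBoundaries:
    """5%/95% lesion boundaries; ``no_lesion`` marks a profile that never
    drops below the 95% threshold.  ``outer_fallback`` flags an outer
    surface taken as the start of coverage because no 5% crossing exists."""

    outer: float | None
    inner: float | None
    no_lesion: bool = False
    outer_fallback: bool = False

    @property
    def lesion_depth(self) -> float:
        if self.no_lesion or self.outer is None or self.inner is None:
            return 0.0
        return self.inner - self.outer


@dataclass
class LesionMetrics:
    """Per-specimen metric set (one analysis line, or the average of lines)."""

    ca_loss: float
    f_uptake_before: float
    f_uptake_after: float
    f_penetration_before: float
    f_penetration_after: float
    intact_ca_mean: float
    outer_surface_before: float | None = None
    inner_surface_before: float | None = None
    outer_surface_after: float | None = None
    inner_surface_after: float | None = None
    mineral_loss: float | None = None
    f_lod: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d


def bin_profile(
    profile: DepthProfile, cfg: AnalysisConfig, ref_pos: float
) -> BinnedProfile:
    """Average a profile in ``cfg.bin_width`` bins anchored at ``ref_pos``
    and extending outward (toward the surface).

    Bin k covers [ref − (k+1)·w, ref − k·w); the bin value is the mean of
    the covered (non-missing) points; empty bins are flagged missing.
    Points at or beyond the reference are not binned.
    """
    pos, val = profile.valid()
    if pos.size == 0:
        raise InputError("cannot bin an empty profile")
    if pos.size > 1:
        spacing = float(np.median(np.diff(pos)))
        if spacing > cfg.bin_width * (1 + 1e-9):
            raise InputError(
                f"profile spacing {spacing:g} um coarser than bin width "
                f"{cfg.bin_width:g} um"
            )
    w = cfg.bin_width
    in_range = pos < ref_pos
    if not np.any(in_range):
        raise InputError("no profile points below the reference position")
    n_bins = int(np.ceil((ref_pos - pos[in_range].min()) / w))
    lower_edges = ref_pos - w * np.arange(n_bins, 0, -1)
    idx = np.floor((pos[in_range] - lower_edges[0]) / w).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[ok], weights=val[in_range][ok], minlength=n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    missing = counts == 0
    values = np.divide(sums, counts, out=np.zeros(n_bins), where=~missing)
    return BinnedProfile(
        lower_edges=lower_edges,
        width=w,
        values=values,
        missing=missing,
        quantity=profile.quantity,
        unit=profile.unit,
    )


def intact_ca(
    profile: DepthProfile | BinnedProfile, cfg: AnalysisConfig, ref_pos: float
) -> float:
    """Mean concentration over the intact-dentin window
    [ref − intact_window, ref] adjacent to the Cu reference."""
    pos, val = _positions_values(profile)
    window = (pos >= ref_pos - cfg.intact_window) & (pos <= ref_pos)
    if not np.any(window):
        raise InputError(
            f"intact window [{ref_pos - cfg.intact_window:g}, {ref_pos:g}] um "
            "contains no data"
        )
    return float(np.mean(val[window]))


def find_boundaries(
    profile: DepthProfile | BinnedProfile, intact: float, cfg: AnalysisConfig
) -> LesionBoundaries:
    """Locate the 5%/95% lesion boundaries by linear interpolation.

    Scanning inward (increasing depth): the outer surface is the first
    crossing of ``outer_frac·intact``, the inner surface the first crossing
    of ``inner_frac·intact`` at or after the outer surface.  A profile never
    below the 95% threshold is a no-lesion result; one entirely below the 5%
    threshold (scan never reaches the tooth) is an error.  A profile that
    starts above the 5% threshold with no crossing takes the start of
    coverage as outer surface (``outer_fallback``).
    """
    if intact <= 0:
        raise InputError("intact Ca mean must be positive")
    pos, val = _positions_values(profile)
    if pos.size < 2:
        raise InputError("need at least two points to locate boundaries")
    lo = cfg.outer_frac * intact
    hi = cfg.inner_frac * intact
    if np.all(val < lo):
        raise InputError("profile entirely below the outer threshold; "
                         "scan does not reach the tooth")
    if np.all(val >= hi):
        return LesionBoundaries(outer=None, inner=None, no_lesion=True)
    outer = _first_upcrossing(pos, val, lo, start=pos[0])
    fallback = False
    if outer is None:
        outer = float(pos[0])
        fallback = True
    inner = _first_upcrossing(pos, val, hi, start=outer)
    return LesionBoundaries(outer=outer, inner=inner, outer_fallback=fallback)


def _first_upcrossing(
    pos: np.ndarray, val: np.ndarray, level: float, start: float
) -> float | None:
    """First linearly-interpolated position >= ``start`` where the profile
    rises through ``level``.  Returns None when the profile is already at or
    above ``level`` at the start of coverage (no crossing from below) or
    never reaches it."""
    if pos[0] >= start and val[0] >= level:
        return None
    for i in range(1, pos.size):
        if val[i - 1] < level <= val[i]:
            frac = (level - val[i - 1]) / (val[i] - val[i - 1])
            x = pos[i - 1] + frac * (pos[i] - pos[i - 1])
            if x >= start:
                return float(x)
    return None


def _positions_values(
    profile: DepthProfile | BinnedProfile,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, BinnedProfile):
        keep = ~profile.missing
        return profile.centers[keep], profile.values[keep]
    return profile.valid()


def _common_bins(
    a: BinnedProfile, b: BinnedProfile
) -> tuple[BinnedProfile, BinnedProfile]:
    """Trim two binned profiles (same width and reference anchor) to their
    shared bin lattice."""
    if a.width != b.width:
        raise InputError("binned profiles have different bin widths")
    if abs(a.reference - b.reference) > 1e-9 * max(1.0, abs(a.reference)):
        raise InputError("binned profiles are anchored at different references")
    if a.lower_edges.size == b.lower_edges.size:
        return a, b
    n = min(a.lower_edges.size, b.lower_edges.size)

    def _trim(p: BinnedProfile) -> BinnedProfile:
        return BinnedProfile(
            lower_edges=p.lower_edges[-n:], width=p.width,
            values=p.values[-n:], missing=p.missing[-n:],
            quantity=p.quantity, unit=p.unit,
        )

    return _trim(a), _trim(b)


def _integrated_difference(
    binned_before: BinnedProfile,
    binned_after: BinnedProfile,
    lo: float,
    hi: float,
    clamp_nonnegative: bool,
) -> float:
    """Rectangle-rule sum of (before − after)·width over bins with centers
    in [lo, hi]; bins missing in either profile are excluded."""
    binned_before, binned_after = _common_bins(binned_before, binned_after)
    centers = binned_before.centers
    sel = (centers >= lo) & (centers <= hi) & ~binned_before.missing \
        & ~binned_after.missing
    if not np.any(sel):
        raise InsufficientOverlapError(
            f"no covered bins in integration region [{lo:g}, {hi:g}] um"
        )
    diff = binned_before.values[sel] - binned_after.values[sel]
    total = float(np.sum(diff) * binned_before.width)
    if clamp_nonnegative:
        total = max(0.0, total)
    return total


def compute_ca_loss(
    pair: SequentialPair, cfg: AnalysisConfig = AnalysisConfig()
) -> float:
    """Integrated Ca loss (wt%·µm): Σ over bins from the before profile's
    outermost surface to the Cu reference of (Ca_before − Ca_after)·width."""
    before, after = pair.profiles["ca"]
    ref = pair.fiducial_position
    bb = bin_profile(before, cfg, ref)
    ba = bin_profile(after, cfg, ref)
    intact = intact_ca(bb, cfg, ref)
    bounds = find_boundaries(bb, intact, cfg)
    outer = _outer_or_coverage_start(bounds, bb)
    return _integrated_difference(bb, ba, outer, ref, cfg.clamp_nonnegative)


def _outer_or_coverage_start(
    bounds: LesionBoundaries, binned: BinnedProfile
) -> float:
    if bounds.outer is not None:
        return bounds.outer
    covered = binned.lower_edges[~binned.missing]
    return float(covered[0]) if covered.size else float(binned.lower_edges[0])


def compute_f_uptake(
    profile: BinnedProfile,
    outer_surface: float,
    ref_pos: float,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> float:
    """F uptake (ppmF·µm): Σ F_bin·width over bins with centers in
    [outer_surface, ref_pos].  Raises if the region holds no covered bins."""
    centers = profile.centers
    sel = (centers >= outer_surface) & (centers <= ref_pos) & ~profile.missing
    if not np.any(sel):
        raise InsufficientOverlapError(
            f"F region [{outer_surface:g}, {ref_pos:g}] um uncovered"
        )
    return float(np.sum(profile.values[sel]) * profile.width)


def compute_f_penetration(
    profile: BinnedProfile,
    outer_surface: float,
    cfg: AnalysisConfig = AnalysisConfig(),
    f_lod: float | None = None,
) -> float:
    """F penetration depth (µm): distance from ``outer_surface`` to the lower
    edge of the first bin (scanning inward) with F below the detection limit.

    0 when the bin containing the surface is already below the limit; the
    full covered depth when no bin falls below it.
    """
    lod = f_lod if f_lod is not None else cfg.f_lod
    if lod is None:
        raise InputError("no F detection limit given (cfg.f_lod or f_lod)")
    sel = np.flatnonzero((profile.centers >= outer_surface) & ~profile.missing)
    if sel.size == 0:
        raise InsufficientOverlapError("no covered bins at or beyond the surface")
    for i in sel:
        if profile.values[i] < lod:
            if i == sel[0]:
                return 0.0
            return max(0.0, float(profile.lower_edges[i]) - outer_surface)
    last = sel[-1]
    return float(profile.lower_edges[last] + profile.width) - outer_surface


def compute_mineral_loss(
    density_before: DepthProfile,
    density_after: DepthProfile,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> float:
    """Integrated mineral loss (mg/cm³·µm) from co-registered µCT density
    profiles: same integral contract as :func:`compute_ca_loss`, with the
    reference point placed ``cfg.uct_region_um`` inside the before profile's
    outermost surface (µCT carries no Cu fiducial)."""
    pos_b, val_b = density_before.valid()
    if pos_b.size < 2:
        raise InputError("uCT before profile too short")
    deep = intact_ca(density_before, cfg,
                     ref_pos=float(pos_b[-1]))  # deep-window plateau mean
    bounds = find_boundaries(density_before, deep, cfg)
    outer = bounds.outer if bounds.outer is not None else float(pos_b[0])
    ref = outer + cfg.uct_region_um
    bb = bin_profile(density_before, cfg, ref)
    ba = bin_profile(density_after, cfg, ref)
    return _integrated_difference(bb, ba, outer, ref, cfg.clamp_nonnegative)


def analyze_specimen(
    before_scan: LineScan,
    after_scan: LineScan,
    curves: Mapping[str, CalibrationCurve],
    cfg: AnalysisConfig = AnalysisConfig(),
    uct_pair: tuple[DepthProfile, DepthProfile] | None = None,
    background_f_counts: float | None = None,
) -> LesionMetrics:
    """Full per-line analysis: calibrate, register, bin, locate boundaries
    and compute every integral metric.

    ``curves`` must contain ``"pixe_ca"`` and ``"pige_f"``; ``uct_pair`` is
    an optional (before, after) pair of density-calibrated µCT profiles.
    The F detection limit is ``cfg.f_lod`` when set, otherwise derived from
    ``background_f_counts`` (estimated from the before scan's intact window
    when not given).
    """
    prof = {}
    for element, kind in (("ca", "pixe_ca"), ("f", "pige_f")):
        prof[element] = (
            apply_calibration(before_scan, curves[kind], element),
            apply_calibration(after_scan, curves[kind], element),
        )
    pair = superimpose(before_scan, after_scan, prof)
    ref = pair.fiducial_position
    ca_b, ca_a = pair.profiles["ca"]
    f_b, f_a = pair.profiles["f"]

    bb_ca = bin_profile(ca_b, cfg, ref)
    ba_ca = bin_profile(ca_a, cfg, ref)
    intact = intact_ca(bb_ca, cfg, ref)
    bounds_b = find_boundaries(bb_ca, intact, cfg)
    bounds_a = find_boundaries(ba_ca, intact, cfg)
    outer_b = _outer_or_coverage_start(bounds_b, bb_ca)
    outer_a = _outer_or_coverage_start(bounds_a, ba_ca)
    ca_loss = _integrated_difference(bb_ca, ba_ca, outer_b, ref,
                                     cfg.clamp_nonnegative)

    lod = cfg.f_lod
    if lod is None:
        if background_f_counts is None:
            window = (before_scan.position_um >= ref - cfg.intact_window) & (
                before_scan.position_um <= ref
            )
            background_f_counts = float(np.median(before_scan.counts_f[window]))
        lod = f_lod_from_background(
            background_f_counts, curves["pige_f"],
            charge=float(np.median(before_scan.charge)),
        )
    bb_f = bin_profile(f_b, cfg, ref)
    ba_f = bin_profile(f_a, cfg, ref)
    up_outer_b = outer_b
    up_outer_a = outer_b if cfg.f_region == "before_surface" else outer_a
    metrics = LesionMetrics(
        ca_loss=ca_loss,
        f_uptake_before=compute_f_uptake(bb_f, up_outer_b, ref, cfg),
        f_uptake_after=compute_f_uptake(ba_f, up_outer_a, ref, cfg),
        f_penetration_before=compute_f_penetration(bb_f, outer_b, cfg, lod),
        f_penetration_after=compute_f_penetration(ba_f, outer_a, cfg, lod),
        intact_ca_mean=intact,
        outer_surface_before=bounds_b.outer,
        inner_surface_before=bounds_b.inner,
        outer_surface_after=bounds_a.outer,
        inner_surface_after=bounds_a.inner,
        f_lod=lod,
        provenance={
            "applied_shift_um": pair.applied_shift,
            "fiducial_position_um": ref,
            "snr_before": pair.fiducial_before.snr if pair.fiducial_before else None,
            "snr_after": pair.fiducial_after.snr if pair.fiducial_after else None,
            "outer_fallback_before": bounds_b.outer_fallback,
            "no_lesion_after": bounds_a.no_lesion,
        },
    )
    if uct_pair is not None:
        metrics.mineral_loss = compute_mineral_loss(uct_pair[0], uct_pair[1], cfg)
    return metrics


def average_metrics(per_line: list[LesionMetrics]) -> LesionMetrics:
    """Average per-line metrics into one specimen-level record (the two
    analysis lines of the protocol are aggregated before cohort statistics).
    Optional fields present in only some lines are averaged over the lines
    that carry them."""
    if not per_line:
        raise InputError("no per-line metrics to average")

    def _mean(name: str) -> float | None:
        vals = [getattr(m, name) for m in per_line if getattr(m, name) is not None]
        return float(np.mean(vals)) if vals else None

    return LesionMetrics(
        ca_loss=_mean("ca_loss"),
        f_uptake_before=_mean("f_uptake_before"),
        f_uptake_after=_mean("f_uptake_after"),
        f_penetration_before=_mean("f_penetration_before"),
        f_penetration_after=_mean("f_penetration_after"),
        intact_ca_mean=_mean("intact_ca_mean"),
        outer_surface_before=_mean("outer_surface_before"),
        inner_surface_before=_mean("inner_surface_before"),
        outer_surface_after=_mean("outer_surface_after"),
        inner_surface_after=_mean("inner_surface_after"),
        mineral_loss=_mean("mineral_loss"),
        f_lod=_mean("f_lod"),
        provenance={"n_lines": len(per_line)},
    )
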