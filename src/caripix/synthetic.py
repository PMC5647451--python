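"""Synthetic paired PIXE/PIGE line scans and µCT profiles of root dentin.

No raw profile data from sequential PIXE/PIGE root-caries experiments are
publicly deposited, so this module provides a fully parametric stand-in with
the statistical structure the downstream analysis assumes:

* a ground-truth specimen (:class:`SpecimenTruth`) whose before-demineralization
  Ca profile is flat sound dentin and whose after profile is surface erosion
  followed by a sigmoid recovery to the sound level;
* an exponentially decaying fluorine uptake profile whose effective decay
  length grows after demineralization (F penetrates deeper through the porous
  demineralized matrix);
* a linear-yield Poisson counting model for the Ca, F and Cu detector
  channels, with a 4 µm Cu fiducial foil at a nominal 800 µm from the outer
  edge rendered as a top-hat convolved with the Gaussian beam spot;
* a cohort generator producing FCM-treated / untreated control specimen pairs
  cut from the same tooth, sharing a per-tooth lesion-severity latent, with
  an optional coupling that attenuates lesion depth in proportion to fluorine
  uptake (reproducing the negative F–Ca-loss association seen in fluoride
  intervention studies);
* a µCT grey-value simulator sharing the same mineral ground truth, so the
  PIXE Ca-loss and µCT mineral-loss channels are correlated by construction.

Every simulator is a pure function of its parameters and seed, and every one
has a ``noise_free`` mode that reproduces the analytic truth exactly — the
basis for round-trip tests of the calibration and metrics stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr

from .errors import InputError
from .profiles import DepthProfile, LineScan

_SIGMA_PER_FWHM = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Default (mean, sd) of each ground-truth parameter across a cohort.
#: Ca of sound dentin ~27 wt%; lesion depths of order 100–200 µm and F
#: surface loads of a few hundred ppm are typical of short in-vitro
#: root-dentin demineralization protocols.
DEFAULT_TRUTH_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "ca_sound": (27.0, 1.0),
    "ca_surface_after": (8.0, 2.0),
    "lesion_mid": (150.0, 40.0),
    "lesion_width": (20.0, 5.0),
    "erosion": (20.0, 8.0),
    "f_amplitude": (200.0, 60.0),
    "f_decay": (50.0, 15.0),
}

#: Hard floors keeping sampled truths physically meaningful.
_TRUTH_FLOORS = {
    "ca_sound": 5.0,
    "ca_surface_after": 0.0,
    "lesion_mid": 10.0,
    "lesion_width": 2.0,
    "erosion": 0.0,
    "f_amplitude": 0.0,
    "f_decay": 5.0,
}


@dataclass(frozen=True)
class SpecimenTruth:
    """Noise-free ground truth for one root-dentin specimen.

    Parameters
    ----------
    ca_sound : wt% Ca of intact dentin.
    ca_surface_after : wt% Ca at the lesion surface after demineralization.
    lesion_mid : µm, sigmoid midpoint of the after-profile measured from the
        receded surface.
    lesion_width : µm, sigmoid width.
    erosion : µm of outright surface recession (material removed).
    f_amplitude : ppm F at the surface (0 for untreated controls).
    f_decay : µm, exponential decay length of the F profile before
        demineralization.
    f_depth_gain : multiplier (≥ 1) on ``f_decay`` after demineralization —
        F reaches deeper through the porous demineralized matrix.
    f_background : ppm, additive F background concentration.
    group : ``"FCM"`` (fluoride-containing material applied) or ``"control"``.
    fiducial_pos : µm, Cu-foil center measured from the original outer edge
        of the exposed root dentin (nominally 800 µm).
    """

    ca_sound: float = 27.0
    ca_surface_after: float = 8.0
    lesion_mid: float = 150.0
    lesion_width: float = 20.0
    erosion: float = 20.0
    f_amplitude: float = 200.0
    f_decay: float = 50.0
    f_depth_gain: float = 1.8
    f_background: float = 0.0
    group: str = "FCM"
    fiducial_pos: float = 800.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ca_surface_after <= self.ca_sound):
            raise InputError(
                "require 0 <= ca_surface_after <= ca_sound, got "
                f"{self.ca_surface_after} vs {self.ca_sound}"
            )
        if self.lesion_width <= 0:
            raise InputError("lesion_width must be positive")
        if self.f_amplitude < 0 or self.f_background < 0:
            raise InputError("F amplitude/background must be non-negative")
        if self.f_decay <= 0:
            raise InputError("f_decay must be positive")
        if self.f_depth_gain < 1.0:
            raise InputError("f_depth_gain must be >= 1")
        if self.erosion < 0:
            raise InputError("erosion must be non-negative")
        if self.group not in ("FCM", "control"):
            raise InputError(f"group must be 'FCM' or 'control', got {self.group!r}")


@dataclass(frozen=True)
class BeamConfig:
    """Scan geometry and linear-yield counting model of the beamline.

    ``step`` and ``spot_fwhm`` default to 10 µm (beam spot below 10 µm in the
    reference setup).  Yields are counts per unit concentration per unit
    charge; backgrounds are mean counts per unit charge.  Numeric values are
    generator defaults, not estimates of any particular instrument.
    """

    step: float = 10.0
    spot_fwhm: float = 10.0
    charge_per_point: float = 1.0
    yield_ca: float = 400.0      # counts per (wt% · charge)
    yield_f: float = 0.5         # counts per (ppm · charge)
    yield_cu: float = 5000.0     # counts per charge with beam fully on foil
    background_ca: float = 2.0
    background_f: float = 9.0
    background_cu: float = 2.0
    foil_width: float = 4.0      # µm, Cu foil thickness seen edge-on
    # half-step start so scan points sample the centers of the 10 µm
    # analysis bins (midpoint rule) when offsets are small
    scan_start: float = -55.0    # µm, stage coordinate of first point
    scan_end: float = 995.0      # µm, stage coordinate of last point

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InputError("step must be positive")
        if self.spot_fwhm <= 0:
            raise InputError("spot_fwhm must be positive")
        for name in ("yield_ca", "yield_f", "yield_cu"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.charge_per_point <= 0:
            raise InputError("charge_per_point must be positive")
        if self.scan_end <= self.scan_start:
            raise InputError("scan_end must exceed scan_start")

    def positions(self) -> np.ndarray:
        """Stage coordinates of the scan points."""
        n = int(math.floor((self.scan_end - self.scan_start) / self.step)) + 1
        return self.scan_start + self.step * np.arange(n)


@dataclass(frozen=True)
class UctConfig:
    """Ground-truth affine grey model of the µCT scanner.

    grey = gain · density + intercept + N(0, noise_sd).  ``step`` defaults to
    the 8.1 µm voxel size of the reference scanner; ``density_sound`` maps
    intact dentin (truth ``ca_sound``) to a nominal mineral density.
    """

    gain: float = 2.0            # grey per (mg/cm³)
    intercept: float = 10.0
    noise_sd: float = 5.0
    step: float = 8.1            # µm
    density_sound: float = 1100.0  # mg/cm³ for intact dentin
    scan_start: float = -50.0
    scan_end: float = 1000.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InputError("uCT gain must be positive")
        if self.noise_sd < 0:
            raise InputError("uCT noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: paired FCM/control specimens cut from identical teeth.

    ``coupling_kappa`` ∈ [0, 1] attenuates the FCM specimen's ``lesion_mid``
    by ``1 − kappa·min(f_amplitude/f_ref, 1)``: more fluorine → shallower
    lesion.  ``severity_sd`` scales a per-tooth lesion-severity latent shared
    by both members of a pair (set 0 for fully independent specimens).
    ``offset_sd`` is the scale (µm) of the rigid stage offset drawn
    independently for every scan, which registration must undo.
    """

    n_pairs: int = 9
    seed: int = 0
    truth_param_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_DISTRIBUTIONS)
    )
    coupling_kappa: float = 0.6
    f_ref: float = 200.0
    severity_sd: float = 0.25
    offset_sd: float = 20.0
    n_lines: int = 2
    f_depth_gain: float = 1.8
    beam: BeamConfig = field(default_factory=BeamConfig)
    uct: UctConfig = field(default_factory=UctConfig)

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise InputError("n_pairs must be >= 1")
        if not (0.0 <= self.coupling_kappa <= 1.0):
            raise InputError("coupling_kappa must lie in [0, 1]")
        if self.offset_sd < 0 or self.severity_sd < 0:
            raise InputError("offset_sd and severity_sd must be non-negative")
        if self.n_lines < 1:
            raise InputError("n_lines must be >= 1")
        if self.f_ref <= 0:
            raise InputError("f_ref must be positive")
        for name, ms in self.truth_param_distributions.items():
            if name not in DEFAULT_TRUTH_DISTRIBUTIONS:
                raise InputError(f"unknown truth parameter {name!r}")
            mean, sd = ms
            if sd < 0:
                raise InputError(f"negative sd for truth parameter {name!r}")
            if not np.isfinite(mean) or not np.isfinite(sd):
                raise InputError(f"non-finite distribution for {name!r}")


# ---------------------------------------------------------------------------
# Analytic truth functions


def true_ca_profile(truth: SpecimenTruth, when: str, z) -> np.ndarray:
    """Noise-free Ca concentration (wt%) at depth(s) ``z`` µm from the
    original outer edge.

    Before demineralization the profile is flat at ``ca_sound``.  After, the
    eroded region ``z < erosion`` holds no material (0 wt%), and deeper the
    profile rises sigmoidally from ``ca_surface_after`` at the receded
    surface back to ``ca_sound``.
    """
    _check_when(when)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise InputError("depth z must be non-negative")
    if when == "before":
        return np.full_like(z, truth.ca_sound)
    u = (z - truth.erosion - truth.lesion_mid) / truth.lesion_width
    prof = truth.ca_surface_after + (truth.ca_sound - truth.ca_surface_after) * expit(u)
    return np.where(z < truth.erosion, 0.0, prof)


def true_f_profile(truth: SpecimenTruth, when: str, z) -> np.ndarray:
    """Noise-free F concentration (ppm) at depth(s) ``z`` µm.

    Exponential decay ``f_amplitude·exp(−z/λ_eff) + f_background`` with
    λ_eff = ``f_decay`` before demineralization and ``f_decay·f_depth_gain``
    after.  After demineralization the eroded region carries background only.
    """
    _check_when(when)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise InputError("depth z must be non-negative")
    lam = truth.f_decay if when == "before" else truth.f_decay * truth.f_depth_gain
    prof = truth.f_amplitude * np.exp(-z / lam) + truth.f_background
    if when == "after":
        prof = np.where(z < truth.erosion, truth.f_background, prof)
    return prof


def true_mineral_density(truth: SpecimenTruth, when: str, z,
                         density_sound: float = 1100.0) -> np.ndarray:
    """Mineral density (mg/cm³) sharing the Ca profile's ground truth."""
    return true_ca_profile(truth, when, z) * (density_sound / truth.ca_sound)


def true_ca_loss(truth: SpecimenTruth, ref: float | None = None) -> float:
    """Closed-form integral ∫₀^ref (Ca_before − Ca_after) dz in wt%·µm.

    Serves as the analytic oracle for the estimated Ca loss.  ``ref``
    defaults to the fiducial position (the Cu reference point).
    """
    R = truth.fiducial_pos if ref is None else float(ref)
    e, m, w = truth.erosion, truth.lesion_mid, truth.lesion_width
    cs, c0 = truth.ca_sound, truth.ca_surface_after
    if R <= e:
        return cs * R
    # over [e, R]: integrand = (cs - c0) * (1 - sigmoid((z - e - m)/w))
    u1 = -m / w
    u2 = (R - e - m) / w
    tail = w * (np.logaddexp(0.0, -u1) - np.logaddexp(0.0, -u2))
    return cs * e + (cs - c0) * float(tail)


def true_f_uptake(truth: SpecimenTruth, when: str, ref: float | None = None) -> float:
    """Closed-form ∫₀^ref F(z) dz in ppm·µm (background included)."""
    _check_when(when)
    R = truth.fiducial_pos if ref is None else float(ref)
    lam = truth.f_decay if when == "before" else truth.f_decay * truth.f_depth_gain
    lo = 0.0 if when == "before" else min(truth.erosion, R)
    integral = truth.f_amplitude * lam * (math.exp(-lo / lam) - math.exp(-R / lam))
    return integral + truth.f_background * R


def _check_when(when: str) -> None:
    if when not in ("before", "after"):
        raise InputError(f"'when' must be 'before' or 'after', got {when!r}")


# ---------------------------------------------------------------------------
# Simulators


def _foil_fraction(z: np.ndarray, truth: SpecimenTruth, beam: BeamConfig) -> np.ndarray:
    """Fraction of the Gaussian beam spot intersecting the Cu foil.

    The foil is a ``foil_width`` top-hat centred at ``fiducial_pos``; the
    beam profile is Gaussian with ``spot_fwhm``; their convolution is a
    difference of normal CDFs.
    """
    sigma = beam.spot_fwhm * _SIGMA_PER_FWHM
    half = 0.5 * beam.foil_width
    x = z - truth.fiducial_pos
    return ndtr((x + half) / sigma) - ndtr((x - half) / sigma)


def simulate_linescan(
    truth: SpecimenTruth,
    beam: BeamConfig,
    when: str,
    offset: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    noise_free: bool = False,
) -> LineScan:
    """Simulate one PIXE/PIGE line scan.

    ``offset`` rigidly shifts the specimen relative to the stage: a point at
    stage coordinate p probes specimen depth z = p − offset (z < 0 is off
    the specimen and yields background only).  Counts in each channel are
    Poisson with mean ``yield·concentration·charge + background·charge``;
    with ``noise_free=True`` the counts equal their means exactly (documented
    variance-suppressed mode used by round-trip tests).

    Identical (truth, beam, when, offset, seed) give identical output.
    """
    _check_when(when)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = beam.positions()
    z = p - offset
    on = z >= 0.0
    zc = np.where(on, z, 0.0)
    ca = np.where(on, true_ca_profile(truth, when, zc), 0.0)
    f = np.where(on, true_f_profile(truth, when, zc), 0.0)
    charge = np.full(p.size, beam.charge_per_point)
    mean_ca = (beam.yield_ca * ca + beam.background_ca) * charge
    mean_f = (beam.yield_f * f + beam.background_f) * charge
    mean_cu = (beam.yield_cu * _foil_fraction(z, truth, beam)
               + beam.background_cu) * charge
    if noise_free:
        counts = (mean_ca, mean_f, mean_cu)
    else:
        counts = tuple(rng.poisson(m).astype(float) for m in (mean_ca, mean_f, mean_cu))
    return LineScan(p, counts[0], counts[1], counts[2], charge)


def simulate_uct_profile(
    truth: SpecimenTruth,
    when: str,
    uct: UctConfig,
    seed: int | np.random.Generator | None = 0,
    noise_free: bool = False,
) -> DepthProfile:
    """Simulate a µCT grey-value line profile in the reconstruction frame.

    grey = gain·density + intercept + N(0, noise_sd), where density shares
    the Ca ground truth (intact dentin maps to ``density_sound``).  Positions
    z < 0 are air (zero density).  Deterministic per seed.
    """
    _check_when(when)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(math.floor((uct.scan_end - uct.scan_start) / uct.step)) + 1
    z = uct.scan_start + uct.step * np.arange(n)
    on = z >= 0.0
    dens = np.where(
        on, true_mineral_density(truth, when, np.where(on, z, 0.0), uct.density_sound), 0.0
    )
    grey = uct.gain * dens + uct.intercept
    if not noise_free and uct.noise_sd > 0:
        grey = grey + rng.normal(0.0, uct.noise_sd, size=n)
    return DepthProfile(z, grey, quantity="grey", unit="grey")


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class SimulatedLine:
    """One analysis line: before/after scans with their true stage offsets."""

    line_id: int
    before: LineScan
    after: LineScan
    offset_before: float
    offset_after: float


@dataclass
class SimulatedSpecimen:
    specimen_id: str
    tooth_id: int
    truth: SpecimenTruth
    lines: list[SimulatedLine]
    uct_before: DepthProfile
    uct_after: DepthProfile


@dataclass
class ToothPair:
    tooth_id: int
    fcm: SimulatedSpecimen
    control: SimulatedSpecimen


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    pairs: list[ToothPair]

    @property
    def specimens(self) -> list[SimulatedSpecimen]:
        out: list[SimulatedSpecimen] = []
        for p in self.pairs:
            out.extend((p.fcm, p.control))
        return out


def sample_truths(spec: CohortSpec, rng: np.random.Generator
                  ) -> list[tuple[SpecimenTruth, SpecimenTruth]]:
    """Draw (FCM, control) ground-truth pairs.

    Each tooth carries a severity latent ``s ~ N(1, severity_sd)`` (floored
    at 0.3) multiplying ``lesion_mid`` of both members; all other parameters
    are independent per specimen.  The FCM member's ``lesion_mid`` is further
    scaled by ``1 − kappa·min(f_amplitude/f_ref, 1)``.
    """
    dists = dict(DEFAULT_TRUTH_DISTRIBUTIONS)
    dists.update(spec.truth_param_distributions)
    pairs = []
    for _ in range(spec.n_pairs):
        severity = max(0.3, 1.0 + spec.severity_sd * rng.standard_normal())
        members = {}
        for group in ("FCM", "control"):
            params = {}
            for name, (mean, sd) in dists.items():
                val = mean + sd * rng.standard_normal()
                params[name] = max(_TRUTH_FLOORS[name], val)
            params["ca_surface_after"] = min(
                params["ca_surface_after"], params["ca_sound"]
            )
            params["lesion_mid"] *= severity
            if group == "control":
                params["f_amplitude"] = 0.0
            else:
                atten = 1.0 - spec.coupling_kappa * min(
                    params["f_amplitude"] / spec.f_ref, 1.0
                )
                params["lesion_mid"] = max(
                    _TRUTH_FLOORS["lesion_mid"], params["lesion_mid"] * atten
                )
            members[group] = SpecimenTruth(
                group=group, f_depth_gain=spec.f_depth_gain, **params
            )
        pairs.append((members["FCM"], members["control"]))
    return pairs


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full cohort: paired truths plus simulated before/after
    line scans (``n_lines`` per specimen, independent rigid stage offsets
    ~ N(0, offset_sd) per scan) and µCT profiles.

    A single master seed (``spec.seed``) spawns independent per-specimen
    streams, so the cohort is reproducible as a whole and per specimen.
    """
    master = np.random.default_rng(spec.seed)
    truths = sample_truths(spec, master)
    streams = master.spawn(2 * spec.n_pairs)
    pairs: list[ToothPair] = []
    for t, (fcm_truth, ctl_truth) in enumerate(truths):
        members = {}
        for k, truth in enumerate((fcm_truth, ctl_truth)):
            rng = streams[2 * t + k]
            lines = []
            for li in range(spec.n_lines):
                ob, oa = rng.normal(0.0, spec.offset_sd, size=2)
                before = simulate_linescan(truth, spec.beam, "before", ob, rng)
                after = simulate_linescan(truth, spec.beam, "after", oa, rng)
                lines.append(SimulatedLine(li, before, after, float(ob), float(oa)))
            uct_b = simulate_uct_profile(truth, "before", spec.uct, rng)
            uct_a = simulate_uct_profile(truth, "after", spec.uct, rng)
            sid = f"T{t:02d}_{truth.group}"
            members[truth.group] = SimulatedSpecimen(
                sid, t, truth, lines, uct_b, uct_a
            )
        pairs.append(ToothPair(t, members["FCM"], members["control"]))
    return SimulatedCohort(spec, pairs)
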