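"""Surface-pressure mechanics: compressibility modulus, phase features,
surface-potential and dipole readouts.

The central quantity is the in-plane elasticity (compressibility modulus)

    C_s⁻¹ = −A · (∂π/∂A)

computed by central differences on the smoothed π–A record.  High C_s⁻¹
means rigid packing (condensed film), low C_s⁻¹ a fluid film; phase
coexistence plateaus show up as near-zero valleys between two C_s⁻¹ maxima.
The detectors below formalize the per-curve readouts customarily quoted for
a compression run: lift-off area, LE–LC transition interval, collapse
point, modulus maxima, condensed-state surface potential, and the apparent
normal dipole moment per molecule from the Helmholtz capacitor model.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .constants import DIPOLE_MD_PER_A2_MV, LIFTOFF_PRESSURE_THRESHOLD
from .errors import InsufficientDataError
from .io import CompressionIsotherm
from .smoothing import SmoothingConfig, adjacent_average, effective_window, prepare_for_derivative

logger = logging.getLogger(__name__)

#: Elasticity bands used to label the film state from C_s⁻¹ (mN/m).
PHASE_BANDS = (
    (12.5, "gaseous/LE-LC"),
    (100.0, "liquid-expanded"),
    (250.0, "liquid-condensed"),
    (float("inf"), "solid"),
)


def phase_label(modulus: float) -> str:
    for upper, label in PHASE_BANDS:
        if modulus < upper:
            return label
    return "solid"


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the feature-extraction pipeline.

    ``smoothing_window``: points of adjacent averaging applied to π and Δψ
    before differentiation (default 50).
    ``liftoff_threshold``: pressure floor (mN/m) below which the modulus is
    not evaluated, and the anchor used by synthetic backbones.
    ``reference_pressure``: where the modulus is compared across curves
    (30 mN/m, the packing pressure of biological membranes; 35 is the
    other end of the customary range).
    ``potential_area_window``: (low, high) Å² window for the condensed-state
    Δψ readout; None picks the per-lipid default, or the whole record if
    the lipid is unknown.
    """

    smoothing_window: int = 50
    liftoff_threshold: float = LIFTOFF_PRESSURE_THRESHOLD
    reference_pressure: float = 30.0
    transition_modulus_threshold: float = 50.0
    collapse_prominence: float = 0.5
    potential_area_window: Optional[tuple[float, float]] = None
    smooth_modulus_for_detection: bool = True


@dataclass
class CompressibilityCurve:
    """(π, C_s⁻¹) pairs with the aligned area grid, in compression order."""

    pressure: np.ndarray
    modulus: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, float)
        self.modulus = np.asarray(self.modulus, float)
        self.area = np.asarray(self.area, float)
        if not (len(self.pressure) == len(self.modulus) == len(self.area)):
            raise InsufficientDataError("curve sequences must be aligned")

    def __len__(self) -> int:
        return len(self.pressure)


@dataclass
class DipoleProfile:
    """Apparent normal dipole moment per molecule (millidebye) vs area."""

    area: np.ndarray
    dipole: np.ndarray


@dataclass
class MonolayerFeatureSet:
    """One summary-table row for a single compression run.

    Absent features (film never lifted off, no coexistence plateau, run
    truncated before collapse, no potential channel) are ``None``.
    ``reported_dipole_area`` is an optional pass-through for the
    experimentally quoted 'surface dipole moment area'; nothing computes it.
    """

    liftoff_area: Optional[float] = None
    collapse_pressure: Optional[float] = None
    collapse_area: Optional[float] = None
    transition_onset_pressure: Optional[float] = None
    transition_end_pressure: Optional[float] = None
    max_modulus: Optional[float] = None
    pressure_at_max_modulus: Optional[float] = None
    modulus_at_reference: Optional[float] = None
    reference_pressure: float = 30.0
    phase_label_at_reference: Optional[str] = None
    max_potential: Optional[float] = None
    area_at_max_potential: Optional[float] = None
    reported_dipole_area: Optional[float] = None

    def to_dict(self) -> dict:
        """Serialize with explicit units in the field names."""
        return {
            "liftoff_area_A2_per_molecule": self.liftoff_area,
            "collapse_pressure_mN_per_m": self.collapse_pressure,
            "collapse_area_A2_per_molecule": self.collapse_area,
            "transition_onset_pressure_mN_per_m": self.transition_onset_pressure,
            "transition_end_pressure_mN_per_m": self.transition_end_pressure,
            "max_modulus_mN_per_m": self.max_modulus,
            "pressure_at_max_modulus_mN_per_m": self.pressure_at_max_modulus,
            "modulus_at_reference_mN_per_m": self.modulus_at_reference,
            "reference_pressure_mN_per_m": self.reference_pressure,
            "phase_label_at_reference": self.phase_label_at_reference,
            "max_potential_mV": self.max_potential,
            "area_at_max_potential_A2_per_molecule": self.area_at_max_potential,
            "reported_dipole_area_A2_per_molecule": self.reported_dipole_area,
        }


def surface_pressure_from_tension(gamma0: float, gamma: float) -> float:
    """Surface pressure π = γ₀ − γ (mN/m): the film's reduction of the
    clean-subphase surface tension."""
    return gamma0 - gamma


def compute_compressibility(
    iso: CompressionIsotherm, liftoff_threshold: float = LIFTOFF_PRESSURE_THRESHOLD
) -> CompressibilityCurve:
    """C_s⁻¹ = −A·(∂π/∂A) on the smoothed isotherm.

    The derivative is estimated by central differences on the area grid
    (one-sided at the ends).  The curve starts at the first sample with
    π ≥ ``liftoff_threshold``: in the gas phase π is all baseline noise and
    differencing would only amplify it.
    """
    above = np.nonzero(iso.pressure >= liftoff_threshold)[0]
    if above.size < 3:
        raise InsufficientDataError(
            "fewer than 3 samples above the lift-off threshold"
        )
    i0 = above[0]
    area = iso.area[i0:]
    pressure = iso.pressure[i0:]
    dpi_da = np.gradient(pressure, area)
    modulus = -area * dpi_da
    return CompressibilityCurve(pressure=pressure, modulus=modulus, area=area)


@dataclass(frozen=True)
class LiftoffResult:
    liftoff_area: Optional[float]
    baseline_sd: float


def detect_liftoff(
    iso: CompressionIsotherm,
    min_jump: float = 0.5,
    baseline_fraction: float = 0.10,
) -> LiftoffResult:
    """Largest area at which π rises detectably above the gas baseline.

    The baseline is the median π over the largest-area 10 % of samples,
    with a robust (MAD-based) spread, so collapse spikes or dust artifacts
    cannot shift it.  Lift-off is the largest area whose pressure reaches
    baseline + max(0.5 mN/m, 5×robust SD) and stays above that level for
    the rest of the compression.  Returns an absent result (not an error)
    when no such crossing exists.
    """
    n = len(iso)
    nb = max(int(round(baseline_fraction * n)), 1)
    if nb < 20:
        logger.warning("only %d baseline samples; lift-off baseline is weak", nb)
    base = iso.pressure[:nb]
    med = float(np.median(base))
    robust_sd = 1.4826 * float(np.median(np.abs(base - med)))
    threshold = med + max(min_jump, 5.0 * robust_sd)
    below = np.nonzero(iso.pressure < threshold)[0]
    if below.size == 0:
        # already above threshold everywhere: no gas region to anchor on
        return LiftoffResult(float(iso.area[0]), robust_sd)
    first_stable = below[-1] + 1
    if first_stable >= n:
        return LiftoffResult(None, robust_sd)
    return LiftoffResult(float(iso.area[first_stable]), robust_sd)


@dataclass(frozen=True)
class CollapseResult:
    collapse_pressure: Optional[float]
    collapse_area: Optional[float]


def _refine_peak(
    iso: CompressionIsotherm, peak: int, window: int
) -> tuple[float, float]:
    """Undo the smoothing bias at a collapse corner.

    Adjacent averaging rounds the apex of a kink down by up to
    (s₁+s₂)·w/8, which for a stiff film exceeds the ±1 mN/m accuracy
    expected of a collapse readout, and shifts the smoothed maximum by up
    to w/2 toward the shallower flank.  Outside ±w/2 of the corner the
    moving average reproduces the underlying signal, so the apex is
    recovered by intersecting the tangents of quadratic fits to either
    flank; the flank placement is then re-centered on the estimate and the
    fit repeated once, which removes the peak-shift bias.
    """
    w = effective_window(window)
    n = len(iso)
    fallback = (float(iso.pressure[peak]), float(iso.area[peak]))
    result = fallback
    center = peak
    for _ in range(2):
        half = max(int(0.6 * w) + 2, 5)
        span = max(int(2.2 * w), 3 * half)
        pre = slice(max(center - span, 0), max(center - half, 1))
        post = slice(min(center + half, n - 1), min(center + span, n))
        if (pre.stop - pre.start) < 5 or (post.stop - post.start) < 5:
            return result
        cpre = np.polyfit(iso.area[pre], iso.pressure[pre], 2)
        a_in = iso.area[pre.stop - 1]
        b1 = float(np.polyval(np.polyder(cpre), a_in))
        a1 = float(np.polyval(cpre, a_in)) - b1 * a_in
        cpost = np.polyfit(iso.area[post], iso.pressure[post], 2)
        a_in2 = iso.area[post.start]
        b2 = float(np.polyval(np.polyder(cpost), a_in2))
        a2 = float(np.polyval(cpost, a_in2)) - b2 * a_in2
        if abs(b1 - b2) < 1e-12:
            return result
        a_star = (a2 - a1) / (b1 - b2)
        p_star = a1 + b1 * a_star
        lo = float(iso.area[min(peak + span, n) - 1])
        hi = float(iso.area[max(peak - span, 0)])
        if not (lo <= a_star <= hi) or p_star < iso.pressure[peak] - 0.5:
            return result
        result = (float(p_star), float(a_star))
        center = int(np.argmin(np.abs(iso.area - a_star)))
    return result


def _kink_breakpoint(area: np.ndarray, pressure: np.ndarray) -> tuple[int, float]:
    """Best two-segment piecewise-linear breakpoint (least squares, index
    space); returns (index, slope of the second segment in dπ/dA)."""
    n = len(pressure)
    best = (None, np.inf, 0.0)
    for b in range(5, n - 5):
        sse = 0.0
        for seg in (slice(0, b + 1), slice(b, n)):
            x = area[seg]
            y = pressure[seg]
            coef = np.polyfit(x, y, 1)
            resid = y - np.polyval(coef, x)
            sse += float(resid @ resid)
            slope2 = coef[0]
        if sse < best[1]:
            best = (b, sse, slope2)
    return best[0], best[2]


def detect_collapse(
    iso: CompressionIsotherm,
    curve: CompressibilityCurve,
    prominence: float = 0.5,
    smoothing_window: int = 50,
) -> CollapseResult:
    """Collapse point: the maximum attained pressure of the run.

    Primary route: the first local maximum of π along compression with
    prominence ≥ 0.5 mN/m (5× the typical film-balance resolution), with
    the apex refined by intersecting line fits on both flanks to undo the
    smoothing blur.  If π is monotone to the end of the run, the kink found
    by a two-segment piecewise-linear fit of the final third is used,
    provided the terminal segment is soft (modulus < 25 % of the maximum).
    Absent when the film never condensed (modulus never exceeded 30 mN/m)
    or the run ended before collapse.
    """
    if float(np.nanmax(curve.modulus)) <= 30.0:
        return CollapseResult(None, None)
    peaks, _ = find_peaks(iso.pressure, prominence=prominence)
    if peaks.size:
        p = int(peaks[0])
        p_star, a_star = _refine_peak(iso, p, smoothing_window)
        return CollapseResult(p_star, a_star)
    # monotone: look for a kink in the final third
    n = len(iso)
    tail = slice(2 * n // 3, n)
    area = iso.area[tail]
    pressure = iso.pressure[tail]
    if len(area) < 20:
        return CollapseResult(None, None)
    b, slope2 = _kink_breakpoint(area, pressure)
    if b is None:
        return CollapseResult(None, None)
    a_b = float(area[b])
    terminal_modulus = -a_b * slope2
    max_mod = float(np.nanmax(curve.modulus))
    if terminal_modulus < 0.25 * max_mod:
        return CollapseResult(float(pressure[b]), a_b)
    return CollapseResult(None, None)


@dataclass(frozen=True)
class TransitionResult:
    onset_pressure: Optional[float]
    end_pressure: Optional[float]

    @property
    def present(self) -> bool:
        return self.onset_pressure is not None


def _smoothed_modulus(curve: CompressibilityCurve, window: int) -> np.ndarray:
    w = min(window, max(len(curve) - 1, 1))
    return adjacent_average(curve.modulus, w) if w > 1 else curve.modulus.copy()


def detect_transition(
    curve: CompressibilityCurve,
    modulus_threshold: float = 50.0,
    smoothing_window: int = 50,
    peak_prominence: float = 5.0,
) -> TransitionResult:
    """LE–LC coexistence interval from the modulus valley.

    A first-order two-dimensional transition flattens the isotherm, so
    C_s⁻¹ dips toward zero between the LE shoulder and the LC rise.  The
    detector takes the maximal contiguous π-interval in which C_s⁻¹ stays
    below 50 mN/m while lying between two local maxima of C_s⁻¹; its π
    bounds (threshold crossings, linearly interpolated) are the transition
    onset and end.  Absence is a valid result, not an error.
    """
    if len(curve) < 5:
        return TransitionResult(None, None)
    span = float(np.nanmax(curve.pressure) - np.nanmin(curve.pressure))
    if span < 10.0:
        return TransitionResult(None, None)
    mod = _smoothed_modulus(curve, smoothing_window)
    peaks, _ = find_peaks(mod, prominence=peak_prominence)
    if peaks.size < 2:
        return TransitionResult(None, None)
    below = mod < modulus_threshold
    # contiguous runs of below-threshold samples
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = [int(e) + 1 for e in edges if below[e + 1]]
    ends = [int(e) for e in edges if below[e]]
    runs = []
    for s in starts:
        e_candidates = [e for e in ends if e >= s]
        if not e_candidates:
            continue
        e = min(e_candidates)
        if peaks.min() < s and peaks.max() > e:
            runs.append((s, e))
    if not runs:
        return TransitionResult(None, None)
    s, e = max(runs, key=lambda r: abs(curve.pressure[r[1]] - curve.pressure[r[0]]))

    def crossing(i_out: int, i_in: int) -> float:
        m0, m1 = mod[i_out], mod[i_in]
        if m0 == m1:
            return float(curve.pressure[i_in])
        t = (modulus_threshold - m0) / (m1 - m0)
        return float(curve.pressure[i_out] + t * (curve.pressure[i_in] - curve.pressure[i_out]))

    onset = crossing(s - 1, s) if s > 0 else float(curve.pressure[s])
    end = crossing(e + 1, e) if e + 1 < len(curve) else float(curve.pressure[e])
    return TransitionResult(onset, end)


@dataclass(frozen=True)
class ModulusSummary:
    max_modulus: float
    pressure_at_max: float
    modulus_at_reference: Optional[float]
    phase_label: Optional[str]


def modulus_summary(
    curve: CompressibilityCurve,
    reference_pressure: float = 30.0,
    collapse_pressure: Optional[float] = None,
    smoothing_window: int = 50,
    smooth_for_peak: bool = True,
) -> ModulusSummary:
    """Peak elasticity and the cross-curve reference readout.

    The peak is located on a lightly re-smoothed modulus (differencing
    re-amplifies the noise the π smoothing removed; the second pass only
    serves peak location and leaves the stored curve untouched).  When a
    collapse exists the maximum is taken over π below it.  The modulus at
    the reference pressure (default 30 mN/m) is linearly interpolated, and
    absent if the curve never reaches it.
    """
    if len(curve) == 0:
        raise InsufficientDataError("empty compressibility curve")
    mod = _smoothed_modulus(curve, smoothing_window) if smooth_for_peak else curve.modulus
    stop = int(np.argmax(curve.pressure)) + 1
    sel = slice(0, stop)
    mask = np.ones(stop, dtype=bool)
    if collapse_pressure is not None:
        mask &= curve.pressure[sel] < collapse_pressure
    if not mask.any():
        mask[:] = True
    idx = np.flatnonzero(mask)
    imax = idx[int(np.argmax(mod[idx]))]
    max_modulus = float(mod[imax])
    pressure_at_max = float(curve.pressure[imax])

    pi_asc = np.maximum.accumulate(curve.pressure[sel])
    if reference_pressure > pi_asc[-1] or reference_pressure < pi_asc[0]:
        logger.debug(
            "reference pressure %.1f outside curve range [%.2f, %.2f]",
            reference_pressure, pi_asc[0], pi_asc[-1],
        )
        mod_ref = None
        label = None
    else:
        mod_ref = float(np.interp(reference_pressure, pi_asc, mod[sel]))
        label = phase_label(mod_ref)
    return ModulusSummary(max_modulus, pressure_at_max, mod_ref, label)


@dataclass(frozen=True)
class PotentialResult:
    max_potential: Optional[float]
    area_at_max: Optional[float]


def max_surface_potential(
    iso: CompressionIsotherm,
    area_window: Optional[tuple[float, float]] = None,
    pressure_window: Optional[tuple[float, float]] = None,
) -> PotentialResult:
    """Extremal Δψ inside a condensed-state window.

    The window may be given in area (Å²) or pressure (mN/m); a pressure
    window is mapped to the areas where the compression traverses it.  For
    negative-running potentials the extremum of largest magnitude is
    returned with its sign.  Absent when the record has no potential
    channel.
    """
    if iso.potential is None:
        return PotentialResult(None, None)
    mask = np.ones(len(iso), dtype=bool)
    if pressure_window is not None:
        lo, hi = sorted(pressure_window)
        mask &= (iso.pressure >= lo) & (iso.pressure <= hi)
    if area_window is not None:
        lo, hi = sorted(area_window)
        mask &= (iso.area >= lo) & (iso.area <= hi)
    if not mask.any():
        raise InsufficientDataError("potential window does not overlap the record")
    idx = np.flatnonzero(mask)
    i = idx[int(np.argmax(np.abs(iso.potential[idx])))]
    return PotentialResult(float(iso.potential[i]), float(iso.area[i]))


def dipole_moment_profile(iso: CompressionIsotherm) -> DipoleProfile:
    """Apparent normal dipole moment per molecule, Helmholtz model.

    μ⊥ = ε₀·A·Δψ, which in field units reads
    μ⊥[mD] = A[Å²]·Δψ[mV]/(12π).  The sign of μ⊥ follows Δψ.
    """
    if iso.potential is None:
        raise InsufficientDataError("isotherm has no surface-potential channel")
    if np.any(iso.area <= 0):
        raise InsufficientDataError("dipole profile requires positive areas")
    dipole = iso.area * iso.potential * DIPOLE_MD_PER_A2_MV
    return DipoleProfile(area=iso.area.copy(), dipole=dipole)


def extract_features(
    iso: CompressionIsotherm, config: FeatureConfig = FeatureConfig()
) -> MonolayerFeatureSet:
    """Run smoothing → compressibility → every detector; assemble one row.

    Deterministic given the input record and configuration.  Features whose
    preconditions fail are marked absent rather than raising, so a gas-only
    or truncated record still yields a (sparse) row.
    """
    smoothed = prepare_for_derivative(
        iso, SmoothingConfig(window=config.smoothing_window, apply_to="both")
    )
    lift = detect_liftoff(smoothed)
    out = MonolayerFeatureSet(reference_pressure=config.reference_pressure)
    out.liftoff_area = lift.liftoff_area
    if lift.liftoff_area is None:
        return out

    try:
        curve = compute_compressibility(smoothed, config.liftoff_threshold)
    except InsufficientDataError:
        return out

    coll = detect_collapse(
        smoothed, curve,
        prominence=config.collapse_prominence,
        smoothing_window=config.smoothing_window,
    )
    out.collapse_pressure = coll.collapse_pressure
    out.collapse_area = coll.collapse_area

    trans = detect_transition(
        curve,
        modulus_threshold=config.transition_modulus_threshold,
        smoothing_window=config.smoothing_window,
    )
    out.transition_onset_pressure = trans.onset_pressure
    out.transition_end_pressure = trans.end_pressure

    summ = modulus_summary(
        curve,
        reference_pressure=config.reference_pressure,
        collapse_pressure=coll.collapse_pressure,
        smoothing_window=config.smoothing_window,
        smooth_for_peak=config.smooth_modulus_for_detection,
    )
    out.max_modulus = summ.max_modulus
    out.pressure_at_max_modulus = summ.pressure_at_max
    out.modulus_at_reference = summ.modulus_at_reference
    out.phase_label_at_reference = summ.phase_label

    if smoothed.potential is not None:
        window = config.potential_area_window
        if window is None:
            from .synthetic import POTENTIAL_WINDOWS

            window = POTENTIAL_WINDOWS.get(iso.metadata.lipid)
        try:
            pot = max_surface_potential(smoothed, area_window=window)
        except InsufficientDataError:
            pot = max_surface_potential(smoothed)
        out.max_potential = pot.max_potential
        out.area_at_max_potential = pot.area_at_max
    return out
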