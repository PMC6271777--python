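"""Synthetic π–A / Δψ–A compression isotherms with controlled phase structure.

The generator builds a noiseless piecewise backbone in compression order
(decreasing area) and adds i.i.d. Gaussian measurement noise:

1. **Gas region** — π = 0 for A > A_lift.
2. **Liquid-expanded (LE) region** — the Volmer 2D equation of state
   π(A) = kT/(A − ω) − Π_coh, with the cohesion pressure Π_coh fixed so that
   π(A_lift) equals the lift-off anchor (0.3 mN/m).
3. **Optional LE–LC coexistence plateau** — a low, constant slope from the
   plateau onset pressure π_t to its end pressure.
4. **Liquid-condensed (LC) region** — constant elasticity K_LC via
   π(A) = π₀ + K_LC·ln(A₀/A), which makes C_s⁻¹ ≡ K_LC exactly.  Without a
   plateau the LC branch takes over at the area where the Volmer modulus
   A·kT/(A − ω)² first reaches K_LC, so both π and C_s⁻¹ are continuous at
   the joint.
5. **Collapse** — π is clipped at the collapse pressure π_coll and then
   relaxes with a gentle post-collapse slope, so the collapse point is the
   maximum attained pressure, as read out in film-balance work.

Presets encode the summary feature values reported for the three bacterial
phospholipids (DPPE, DPPG, cardiolipin) on water and on subphases
containing each of five natural antimicrobial compounds; the free shape
parameters (Volmer co-area, area range, potential sigmoid) are solved so
that the standard detectors recover the encoded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import KT_23C, LIFTOFF_PRESSURE_THRESHOLD, kT
from .errors import ParameterInfeasibleError, PresetLookupError
from .io import CompressionIsotherm, IsothermMetadata

__all__ = [
    "SyntheticIsothermSpec",
    "SurfacePotentialSpec",
    "generate_isotherm",
    "noiseless_backbone",
    "preset_spec",
    "preset_metadata",
    "list_presets",
    "PRESET_TABLE",
    "PresetValues",
    "POTENTIAL_WINDOWS",
]


@dataclass(frozen=True)
class SyntheticIsothermSpec:
    """Parameters of the piecewise isotherm generator.

    Areas in Å²/molecule, pressures in mN/m, temperature in °C.  Slopes are
    expressed as dπ/dA along the grid, so during compression (decreasing A)
    a negative ``plateau_slope`` means pressure still creeps up, and a
    positive ``post_collapse_slope`` would mean pressure keeps rising after
    collapse (the default is a gentle relaxation).
    """

    area_max: float = 120.0
    area_min: float = 20.0
    n_points: int = 1000
    liftoff_area: float = 90.0
    volmer_coarea: float = 40.0
    temperature: float = 23.0
    plateau_enabled: bool = False
    plateau_onset_pressure: float = 15.0
    plateau_end_pressure: float = 22.0
    plateau_slope: float = -0.25
    lc_elasticity: float = 200.0
    collapse_pressure: float = 50.0
    post_collapse_slope: float = 0.3
    noise_sd_pressure: float = 0.0
    noise_sd_potential: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.area_max > self.liftoff_area > self.area_min > 0):
            raise ParameterInfeasibleError(
                "need area_max > liftoff_area > area_min > 0"
            )
        if self.volmer_coarea < 0 or self.volmer_coarea >= self.liftoff_area:
            raise ParameterInfeasibleError("need 0 <= volmer_coarea < liftoff_area")
        if self.n_points < 100:
            raise ParameterInfeasibleError("n_points must be >= 100")
        if self.plateau_enabled and not (
            self.collapse_pressure
            > self.plateau_end_pressure
            >= self.plateau_onset_pressure
            >= 0
        ):
            raise ParameterInfeasibleError(
                "need collapse_pressure > plateau_end >= plateau_onset >= 0"
            )
        if self.lc_elasticity <= 0:
            raise ParameterInfeasibleError("lc_elasticity must be > 0")
        if self.collapse_pressure <= 0:
            raise ParameterInfeasibleError("collapse_pressure must be > 0")
        if self.noise_sd_pressure < 0 or self.noise_sd_potential < 0:
            raise ParameterInfeasibleError("noise SDs must be >= 0")


@dataclass(frozen=True)
class SurfacePotentialSpec:
    """Sigmoidal Δψ–A backbone: psi_max/(1 + exp((A − A_ψ)/w_ψ)).

    ``psi_max`` may be negative (inverted-dipole films run negative).
    The potential starts rising at areas around A_ψ — typically before the
    pressure lift-off, as surface potential is sensitive to island
    formation in the gas phase — and saturates at psi_max on compression.
    """

    psi_max: float = 500.0
    midpoint_area: float = 100.0
    width: float = 5.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterInfeasibleError("sigmoid width must be > 0")


@dataclass(frozen=True)
class _Backbone:
    """Analytic description of the noiseless pressure backbone."""

    omega: float
    cohesion_pressure: float
    kT: float
    le_end_area: float  # area where the LE (Volmer) branch hands over
    plateau_end_area: Optional[float]
    lc_start_area: Optional[float]
    lc_start_pressure: Optional[float]
    collapse_area: Optional[float]


def _volmer_modulus_switch(omega: float, k_lc: float, kt: float) -> float:
    """kT/(A−ω) at the area where the Volmer modulus equals k_lc."""
    if omega == 0.0:
        return k_lc
    # modulus = x*(1 + omega*x/kT) with x = kT/(A−ω)
    return kt * (-1.0 + math.sqrt(1.0 + 4.0 * omega * k_lc / kt)) / (2.0 * omega)


def _solve_backbone(spec: SyntheticIsothermSpec) -> _Backbone:
    kt = kT(spec.temperature)
    thresh = LIFTOFF_PRESSURE_THRESHOLD
    d0 = spec.liftoff_area - spec.volmer_coarea
    pi_coh = kt / d0 - thresh
    omega = spec.volmer_coarea

    def volmer_area_at(pressure: float) -> float:
        return omega + kt / (pressure + pi_coh)

    if spec.plateau_enabled:
        a_t = volmer_area_at(spec.plateau_onset_pressure)
        if a_t <= max(spec.area_min, omega):
            raise ParameterInfeasibleError(
                "Volmer branch cannot reach the plateau onset pressure "
                "above area_min (or above the co-area)"
            )
        rise = spec.plateau_end_pressure - spec.plateau_onset_pressure
        slope = -spec.plateau_slope  # dπ per Å² of compression
        if rise > 0 and slope <= 0:
            raise ParameterInfeasibleError(
                "plateau_slope must let pressure rise to plateau_end_pressure"
            )
        a_e = a_t - (rise / slope if rise > 0 else 0.0)
        if a_e <= spec.area_min:
            raise ParameterInfeasibleError("plateau does not end above area_min")
        lc_a, lc_p = a_e, spec.plateau_end_pressure
        le_end = a_t
        plateau_end = a_e
    else:
        x = _volmer_modulus_switch(omega, spec.lc_elasticity, kt)
        lc_p = x - pi_coh
        lc_a = omega + kt / x
        if lc_p <= thresh:
            raise ParameterInfeasibleError(
                "LE modulus already exceeds lc_elasticity at lift-off; "
                "increase the co-area gap or lc_elasticity"
            )
        if lc_p >= spec.collapse_pressure:
            raise ParameterInfeasibleError(
                "Volmer branch reaches the collapse pressure before its "
                "modulus reaches lc_elasticity"
            )
        le_end = lc_a
        plateau_end = None

    if lc_a <= spec.area_min:
        # run truncates while still expanded; no LC branch, no collapse
        if spec.area_min <= omega:
            raise ParameterInfeasibleError(
                "area_min lies at or below the Volmer co-area while the LE "
                "branch is still active"
            )
        return _Backbone(omega, pi_coh, kt, le_end, plateau_end, None, None, None)

    a_coll = lc_a * math.exp(-(spec.collapse_pressure - lc_p) / spec.lc_elasticity)
    if a_coll <= spec.area_min:
        a_coll_eff = None  # collapse not reached within the run
    else:
        a_coll_eff = a_coll
    return _Backbone(omega, pi_coh, kt, le_end, plateau_end, lc_a, lc_p, a_coll_eff)


def noiseless_backbone(spec: SyntheticIsothermSpec) -> tuple[np.ndarray, np.ndarray]:
    """Uniform decreasing area grid and the noiseless pressure backbone."""
    bb = _solve_backbone(spec)
    area = np.linspace(spec.area_max, spec.area_min, spec.n_points)
    pi = np.zeros_like(area)

    le_mask = (area <= spec.liftoff_area) & (area > bb.le_end_area)
    with np.errstate(divide="ignore"):
        pi[le_mask] = bb.kT / (area[le_mask] - bb.omega) - bb.cohesion_pressure

    if spec.plateau_enabled and bb.plateau_end_area is not None:
        pl_mask = (area <= bb.le_end_area) & (area > bb.plateau_end_area)
        slope = -spec.plateau_slope
        pi[pl_mask] = spec.plateau_onset_pressure + slope * (
            bb.le_end_area - area[pl_mask]
        )

    if bb.lc_start_area is not None:
        a_low = bb.collapse_area if bb.collapse_area is not None else spec.area_min - 1.0
        lc_mask = (area <= bb.lc_start_area) & (area > a_low)
        pi[lc_mask] = bb.lc_start_pressure + spec.lc_elasticity * np.log(
            bb.lc_start_area / area[lc_mask]
        )
        pi[lc_mask] = np.minimum(pi[lc_mask], spec.collapse_pressure)
        if bb.collapse_area is not None:
            pc_mask = area <= bb.collapse_area
            pi[pc_mask] = spec.collapse_pressure + spec.post_collapse_slope * (
                area[pc_mask] - bb.collapse_area
            )
            np.clip(pi[pc_mask], 0.0, None, out=pi[pc_mask])
    elif bb.le_end_area < spec.liftoff_area:
        # LE branch runs to the end of the grid
        tail = area <= bb.le_end_area
        pi[tail] = bb.kT / (area[tail] - bb.omega) - bb.cohesion_pressure

    return area, pi


def potential_backbone(
    area: np.ndarray, psi_spec: SurfacePotentialSpec
) -> np.ndarray:
    z = (area - psi_spec.midpoint_area) / psi_spec.width
    return psi_spec.psi_max / (1.0 + np.exp(np.clip(z, -500, 500)))


def generate_isotherm(
    spec: SyntheticIsothermSpec,
    psi_spec: Optional[SurfacePotentialSpec] = None,
    metadata: Optional[IsothermMetadata] = None,
) -> CompressionIsotherm:
    """Generate one synthetic compression isotherm.

    Gaussian noise of the configured SDs is added to π and Δψ; the same
    seed reproduces the output exactly.  Raises
    :class:`ParameterInfeasibleError` when the phase sequence cannot be
    realized (e.g. the Volmer branch cannot reach the plateau onset).
    """
    area, pi = noiseless_backbone(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_pressure > 0:
        pi = pi + rng.normal(0.0, spec.noise_sd_pressure, size=pi.shape)
        # the validated container tolerates baselines down to -1 mN/m only
        np.clip(pi, -0.999, None, out=pi)
    psi = None
    if psi_spec is not None:
        psi = potential_backbone(area, psi_spec)
        if spec.noise_sd_potential > 0:
            psi = psi + rng.normal(0.0, spec.noise_sd_potential, size=psi.shape)
    if metadata is None:
        metadata = IsothermMetadata(source="monofilm synthetic generator")
    return CompressionIsotherm(area=area, pressure=pi, potential=psi, metadata=metadata)


# --------------------------------------------------------------------------
# Presets: summary feature values for 3 lipids x (water + 5 compounds)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PresetValues:
    """Summary-table cell values a preset is built to reproduce.

    ``dipole_area`` is an experimentally reported, loosely defined quantity
    (units Å²/molecule) carried along for completeness; no detector
    computes it.
    """

    liftoff_area: float
    collapse_pressure: float
    max_modulus: float
    max_potential: float
    dipole_area: Optional[float] = None


LIPIDS = ("DPPE", "DPPG", "cardiolipin")
COMPOUNDS = (
    "water",
    "carvacrol",
    "cinnamaldehyde",
    "geraniol",
    "2,5-dihydroxybenzaldehyde",
    "2-hydroxy-5-methoxybenzaldehyde",
)

PRESET_TABLE: dict[tuple[str, str], PresetValues] = {
    ("DPPE", "water"): PresetValues(43, 58, 240, 600, None),
    ("DPPE", "carvacrol"): PresetValues(120, 38, 50, 520, 185),
    ("DPPE", "cinnamaldehyde"): PresetValues(117, 51, 95, 300, 75),
    ("DPPE", "geraniol"): PresetValues(120, 43, 88, 300, 100),
    ("DPPE", "2,5-dihydroxybenzaldehyde"): PresetValues(33, 50, 108, 300, 90),
    ("DPPE", "2-hydroxy-5-methoxybenzaldehyde"): PresetValues(43, 47, 100, 600, 75),
    ("DPPG", "water"): PresetValues(90, 49, 255, 450, 125),
    ("DPPG", "carvacrol"): PresetValues(200, 42, 60, 180, 400),
    ("DPPG", "cinnamaldehyde"): PresetValues(200, 44, 175, 75, 250),
    ("DPPG", "geraniol"): PresetValues(200, 38, 80, 25, 180),
    ("DPPG", "2,5-dihydroxybenzaldehyde"): PresetValues(90, 52, 170, 230, 270),
    ("DPPG", "2-hydroxy-5-methoxybenzaldehyde"): PresetValues(125, 42, 72, 460, 250),
    ("cardiolipin", "water"): PresetValues(110, 52, 145, 270, 260),
    ("cardiolipin", "carvacrol"): PresetValues(180, 39, 85, 280, 400),
    ("cardiolipin", "cinnamaldehyde"): PresetValues(180, 43, 120, 80, 400),
    ("cardiolipin", "geraniol"): PresetValues(180, 32, 90, -100, 250),
    ("cardiolipin", "2,5-dihydroxybenzaldehyde"): PresetValues(140, 52, 130, 430, 320),
    ("cardiolipin", "2-hydroxy-5-methoxybenzaldehyde"): PresetValues(180, 44, 115, 210),
}

#: Default area windows (Å²/molecule) in which the condensed-state maximum
#: surface potential of each lipid is read out.
POTENTIAL_WINDOWS: dict[str, tuple[float, float]] = {
    "DPPE": (30.0, 40.0),
    "DPPG": (40.0, 80.0),
    "cardiolipin": (50.0, 100.0),
}

#: Subphase concentration of each additive (µg/mL); the dihydroxy compound
#: was dosed at its minimum inhibitory concentration, the others at 0.5 mg/mL.
ADDITIVE_CONCENTRATIONS: dict[str, Optional[float]] = {
    "water": None,
    "carvacrol": 500.0,
    "cinnamaldehyde": 500.0,
    "geraniol": 500.0,
    "2,5-dihydroxybenzaldehyde": 74.0,
    "2-hydroxy-5-methoxybenzaldehyde": 500.0,
}

# Minimum LE slope at lift-off (mN/m per Å²): keeps the lift-off of the
# Volmer branch crisp enough that a threshold detector localizes it to a
# few Å², while leaving the branch compliant at higher pressures.
_MIN_LIFTOFF_SLOPE = 0.12
_COLLAPSE_TAIL = 15.0  # Å² of post-collapse record kept by default


def _normalize_preset_key(lipid: str, subphase: str) -> tuple[str, str]:
    lmap = {name.lower(): name for name in LIPIDS}
    cmap = {name.lower(): name for name in COMPOUNDS}
    lk = lmap.get(lipid.strip().lower())
    ck = cmap.get(subphase.strip().lower())
    if lk is None or ck is None:
        raise PresetLookupError(
            f"unknown preset ({lipid!r}, {subphase!r}); valid lipids: "
            f"{list(LIPIDS)}, valid subphases: {list(COMPOUNDS)}"
        )
    return lk, ck


def list_presets() -> list[tuple[str, str]]:
    return list(PRESET_TABLE)


def _solve_coarea(a_lift: float, k_lc: float, pi_coll: float) -> float:
    """Choose the Volmer co-area offset d0 = A_lift − ω for a preset.

    d0 controls the stiffness of the LE branch: small d0 means a sharp
    lift-off but an LE branch whose modulus climbs quickly.  We aim the
    LE→LC handover (where the Volmer modulus reaches K_LC) at roughly a
    quarter of the collapse pressure, subject to the lift-off slope staying
    above _MIN_LIFTOFF_SLOPE (slope at lift-off = kT/d0²).
    """
    kt = KT_23C
    thresh = LIFTOFF_PRESSURE_THRESHOLD
    d0_cap = min(math.sqrt(kt / _MIN_LIFTOFF_SLOPE), 0.95 * a_lift)
    target = min(max(0.25 * pi_coll, 4.0), 15.0)

    def switch_pressure(d0: float) -> float:
        omega = a_lift - d0
        x = _volmer_modulus_switch(omega, k_lc, kt)
        return x - (kt / d0 - thresh)

    if switch_pressure(d0_cap) <= target:
        d0 = d0_cap
    else:
        d0 = brentq(lambda d: switch_pressure(d) - target, 0.5, d0_cap, xtol=1e-6)
    pi_s = switch_pressure(d0)
    if not (thresh < pi_s < pi_coll - 4.0):
        raise ParameterInfeasibleError(
            f"no feasible Volmer co-area for lift-off {a_lift}, "
            f"elasticity {k_lc}, collapse {pi_coll}"
        )
    return d0


def preset_spec(
    lipid: str, subphase: str, *, seed: int = 0, n_points: int = 1000,
    noise_sd_pressure: float = 0.2, noise_sd_potential: float = 5.0,
) -> tuple[SyntheticIsothermSpec, SurfacePotentialSpec]:
    """Generator parameters reproducing one summary-table condition.

    The tabulated lift-off area, collapse pressure, maximal C_s⁻¹ and
    condensed-state surface potential are injected directly; the remaining
    shape parameters (co-area, area range, potential sigmoid) are solved so
    that the feature detectors recover the injected values.
    """
    lk, ck = _normalize_preset_key(lipid, subphase)
    vals = PRESET_TABLE[(lk, ck)]
    a_lift = float(vals.liftoff_area)
    k_lc = float(vals.max_modulus)
    pi_coll = float(vals.collapse_pressure)
    kt = KT_23C
    thresh = LIFTOFF_PRESSURE_THRESHOLD

    d0 = _solve_coarea(a_lift, k_lc, pi_coll)
    omega = a_lift - d0
    x = _volmer_modulus_switch(omega, k_lc, kt)
    pi_s = x - (kt / d0 - thresh)
    a_s = omega + kt / x
    a_coll = a_s * math.exp(-(pi_coll - pi_s) / k_lc)

    win_lo, win_hi = POTENTIAL_WINDOWS[lk]
    width = max(2.0, a_lift / 25.0)
    midpoint = max(1.2 * a_lift, win_hi + 5.0 * width)
    area_max = max(a_lift + max(25.0, 0.35 * a_lift), midpoint + 4.0 * width)
    area_min = min(a_coll - _COLLAPSE_TAIL, win_lo)
    area_min = max(0.5, min(area_min, a_coll - 5.0))

    spec = SyntheticIsothermSpec(
        area_max=area_max,
        area_min=area_min,
        n_points=n_points,
        liftoff_area=a_lift,
        volmer_coarea=omega,
        temperature=23.0,
        plateau_enabled=False,
        lc_elasticity=k_lc,
        collapse_pressure=pi_coll,
        post_collapse_slope=0.3,
        noise_sd_pressure=noise_sd_pressure,
        noise_sd_potential=noise_sd_potential,
        seed=seed,
    )
    psi = SurfacePotentialSpec(
        psi_max=float(vals.max_potential), midpoint_area=midpoint, width=width
    )
    return spec, psi


def preset_metadata(lipid: str, subphase: str) -> IsothermMetadata:
    lk, ck = _normalize_preset_key(lipid, subphase)
    return IsothermMetadata(
        lipid=lk,
        subphase_additive=ck,
        additive_concentration=ADDITIVE_CONCENTRATIONS[ck],
        temperature=23.0,
        compression_rate=21.157,
        trough_area=227.15,
        subphase_volume=100.0,
        source="monofilm synthetic preset",
    )
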