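# Methods

## The measurement being modeled

A Langmuir film balance compresses a one-molecule-thick phospholipid film
at the air–water interface while recording surface pressure π = γ₀ − γ
(mN/m, Wilhelmy-type probe, resolution ~±0.1 mN/m) and, optionally, the
Volta surface potential Δψ (mV, vibrating-plate method) against the area
per molecule A (Å²/molecule).  Compression drives the film through a gas
region (π ≈ 0), a liquid-expanded (LE) fluid phase, sometimes a
first-order LE→liquid-condensed (LC) coexistence plateau, a stiff LC
phase, and finally collapse into the third dimension.  Dissolved
compounds in the subphase shift all of these landmarks; the analysis
quantifies the shifts relative to a water control.

## Analysis pipeline

1. **Canonicalization** (`io`): records are sorted into compression order
   (strictly decreasing A), rows with missing fields dropped,
   duplicate-area rows (barrier pauses) averaged when they are ≤1 % of the
   file, rejected otherwise.  Pressures below −1 mN/m are treated as
   invalid rather than as a tolerable baseline offset.
2. **Smoothing** (`smoothing`): unweighted centered moving average
   ("adjacent averaging"), default 50 points.  A symmetric window needs an
   odd length, so 50 is realized as 51 and logged.  At the edges the
   window shrinks symmetrically — zero padding or trailing windows would
   bias the lift-off and collapse positions via phase lag.  Smoothing is
   applied to π and Δψ as functions of sample index before
   differentiation; on the uniform compression grid this is equivalent to
   smoothing in area.
3. **Modulus** (`features.compute_compressibility`):
   C_s⁻¹ = −A·(∂π/∂A) with central differences on the area grid
   (one-sided at the ends), restricted to π above the lift-off threshold
   (0.3 mN/m) because differencing the gas baseline only amplifies noise.
4. **Detectors** (`features`): see below.
5. **Comparison** (`compare`): per-lipid tables; percent reduction
   100·(control − treatment)/|control| (positive = reduction) and fold
   reduction control ÷ treatment (defined only for two positive values;
   a potential that changes sign has no meaningful fold).  Headline
   numbers round to the nearest integer, ties away from zero.

## Detector definitions and numerical choices

* **Lift-off**: baseline = median π of the largest-area 10 % of samples
  with a MAD-based robust SD (spikes and dust cannot shift a median);
  lift-off is the largest A whose π reaches
  baseline + max(0.5 mN/m, 5×robust SD) and stays above it for the rest
  of the run.  The 0.5 mN/m floor is five times the instrument-scale
  resolution.
* **LE–LC transition**: maximal contiguous π-interval with C_s⁻¹ below
  50 mN/m lying between two local maxima of C_s⁻¹; bounds are the
  threshold crossings, linearly interpolated.  The 50 mN/m threshold
  separates coexistence valleys (C_s⁻¹ near zero) from LE shoulders and is
  configurable.  Absence (no plateau) is a result, not an error.
* **Collapse**: first local maximum of π along compression with prominence
  ≥ 0.5 mN/m.  The moving average rounds a collapse kink down by up to
  (s₁+s₂)·w/8 and shifts its apparent maximum toward the shallower flank
  by up to half a window, so the apex is refined by intersecting flank
  tangents (quadratic fits evaluated at the inner flank edges), with the
  flank placement re-centered once on the first estimate.  If π is
  monotone to the end of the run, a two-segment piecewise-linear fit of
  the final third locates a kink instead, accepted only when the terminal
  segment's modulus falls below 25 % of the curve maximum; otherwise the
  run simply ended before collapse.  Both routes require the film to have
  condensed at all (C_s⁻¹ > 30 mN/m somewhere).
* **Modulus summary**: the peak is located on a re-smoothed copy of the
  modulus curve (same window).  Central differencing re-amplifies the
  noise that the π smoothing suppressed; without the second pass the
  *maximum* of the modulus curve is biased upward by the noise envelope
  (several percent for soft films), which would systematically inflate
  the headline C_s⁻¹ of fluidized monolayers.  The stored curve itself
  remains un-resmoothed.  The modulus at the reference pressure
  (30 mN/m, configurable toward 35) is linearly interpolated on the
  pre-collapse, ascending part of the curve.  Phase labels follow the
  customary elasticity bands: < 12.5 gaseous/coexistence, 12.5–100
  liquid-expanded, 100–250 liquid-condensed, > 250 solid-like.
* **Surface potential**: extremum of largest magnitude (sign preserved)
  of the smoothed Δψ inside a condensed-state window — per-lipid defaults
  DPPE 30–40 Å², DPPG 40–80 Å², cardiolipin 50–100 Å², all configurable;
  a pressure window is also accepted and mapped through the record.
* **Dipole moment**: μ⊥ = ε₀·A·Δψ reported in millidebye via the field's
  12π convention, μ⊥[mD] = A[Å²]·Δψ[mV]/(12π), exact at the unit point
  A = 12π Å², Δψ = 1 mV.  (The convention's constant 1/(12π) differs from
  the CODATA ε₀ route by 0.07 %, far below the measurement's meaning.)

## Synthetic generator

The generator builds a noiseless backbone in compression order and adds
i.i.d. Gaussian noise to π and Δψ:

* gas: π = 0 above the lift-off area;
* LE: Volmer equation of state π = kT/(A − ω) − Π_coh, with the cohesion
  pressure fixed by anchoring π(A_lift) = 0.3 mN/m (the lift-off
  threshold, which makes "lift-off area" well defined even without
  noise).  kT is 408.9 mN·Å²/m at 23 °C, scaled linearly with absolute
  temperature;
* optional coexistence plateau: constant low slope from the onset to the
  end pressure;
* LC: π = π₀ + K_LC·ln(A₀/A), which has C_s⁻¹ ≡ K_LC exactly — the
  injected elasticity is the ground truth the pipeline must recover.
  Without a plateau, the LC branch takes over where the Volmer modulus
  A·kT/(A − ω)² first reaches K_LC, making both π and C_s⁻¹ continuous at
  the joint;
* collapse: π is clipped at the collapse pressure and then relaxes with a
  gentle slope (default 0.3 mN/m per Å² of further compression), so the
  collapse point is the maximum attained pressure — the quantity actually
  quoted from experiments.  No Maxwell construction is attempted for the
  plateau; the generator is phenomenological, not thermodynamic.

Noise is i.i.d. Gaussian per sample (defaults 0.2 mN/m and 5 mV for
presets), consistent with the smoothing-window approach to noise removal;
real instrument drift and autocorrelated vibration are *not* emulated, so
passing recovery tests bounds detector error under white noise only.
Likewise the sigmoidal Δψ backbone (saturating at psi_max during
compression, rising around a midpoint area that may precede the pressure
lift-off, as surface potentials do when islands form) ignores the
non-monotonic humps some real films show.

### Presets

Presets exist for 18 conditions: three lipids (DPPE, DPPG, cardiolipin) ×
water and five antimicrobial compounds (carvacrol, cinnamaldehyde,
geraniol, 2,5-dihydroxybenzaldehyde, 2-hydroxy-5-methoxybenzaldehyde).
Each preset injects the published summary values — lift-off area, collapse
pressure, maximal C_s⁻¹ (used as K_LC), condensed-state surface potential
— directly as generator parameters.  The remaining shape parameters are
solved, not tabulated:

* the Volmer co-area ω is chosen so the LE→LC handover lands near a
  quarter of the collapse pressure, subject to the LE slope at lift-off
  staying above 0.12 mN/m per Å².  The lower bound keeps the lift-off
  crisp enough for threshold detection (±3 Å²); softer, higher-lift-off
  films (the expanded carvacrol/geraniol conditions) sit at this bound.
  A single Volmer branch cannot be simultaneously soft at 15 mN/m and
  sharp at a 200 Å² lift-off, so preset curves do not carry a coexistence
  plateau; plateau behaviour is exercised by explicit plateau specs
  instead (the summary table reports no transition pressures to inject);
* the area range keeps ≳25 % of samples in the gas region for the
  baseline, at least ~15 Å² of post-collapse record for the collapse
  detector, and extends below the lipid's potential window;
* the Δψ sigmoid midpoint and width are placed so the potential is
  saturated throughout the per-lipid readout window.

Preset metadata carry the nominal experimental context (23 °C,
compression rate 21.157 Å²/chain/min, 227.15 cm² trough, 100 mL subphase,
compound concentrations 0.5 mg/mL, or 74 µg/mL for
2,5-dihydroxybenzaldehyde — its minimum inhibitory concentration).

The summary table's "surface dipole moment area" row has area units but no
operational definition; it is carried through reporting as an optional
experimental field (`reported_dipole_area`) and never computed.

## Problem sizes and determinism

Preset curves use 1000 points; oracle checks use 2000–4000-point noiseless
grids so that corner blur (±half a smoothing window) and the curvature
bias of the moving average (~f''·(wh)²/24) stay inside the stated
tolerances.  Parameter-recovery checks run 50 seeds per condition in the
test suite and 20 per condition in the acceptance script; each run draws
its noise from a seeded generator, and identical seeds reproduce records
bit for bit.

## Known limitations

* Detectors assume a single compression run; hysteresis/decompression
  analysis and mixed-monolayer excess thermodynamics are out of scope.
* The lift-off readout is threshold-based; for very gradually rising
  films it sits systematically a little inside the true onset (within the
  ±3 Å² design tolerance for the preset conditions).
* The two-segment kink fallback for collapse is O(n²) in the tail length
  and deliberately simple; runs that end mid-plateau report collapse as
  absent rather than guessing.
* Fold reductions are undefined across sign changes (e.g. a potential
  driven negative); such cells report percent change only.
* The generator's LE branch is a single Volmer fluid: it cannot represent
  both a sharp lift-off at very large areas and a soft approach to a
  mid-pressure plateau, a geometry some strongly expanded real films do
  show.
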