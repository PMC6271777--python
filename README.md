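# monofilm

Analysis of Langmuir monolayer compression isotherms — the π–A
(surface-pressure vs area-per-molecule) and Δψ–A (surface-potential vs
area) records produced by a film balance when a phospholipid monolayer is
compressed at the air–water interface.  The package is aimed at membrane
biophysicists who use monolayers of bacterial phospholipids (DPPE, DPPG,
cardiolipin) as model membranes and ask how dissolved compounds — here,
five natural antimicrobials — change the film's packing, elasticity and
dipole organization.

## What it computes

* **Surface pressure** π = γ₀ − γ, the film's reduction of the clean
  subphase tension (mN/m).
* **Compressibility (elasticity) modulus**

  C_s⁻¹ = −A·(∂π/∂A)

  estimated by central differences after adjacent-averaging smoothing
  (default 50-point window).  High C_s⁻¹ means rigid, tightly packed
  films; a drop under a compound indicates fluidization.
* **Phase features** per curve: lift-off area (where π first rises
  detectably above the gas baseline), the liquid-expanded→liquid-condensed
  (LE–LC) coexistence interval (a near-zero valley of C_s⁻¹ between two of
  its maxima), the collapse point (the maximum attained pressure), the
  modulus maximum and its value at a reference pressure of 30 mN/m (the
  packing pressure of biological membranes), and the condensed-state
  surface-potential extremum.
* **Apparent dipole moment** per molecule from the Helmholtz
  parallel-plate model, μ⊥ = ε₀·A·Δψ, i.e. μ⊥[mD] = A[Å²]·Δψ[mV]/(12π).
* **Control-relative statistics**: per-lipid feature tables, percent
  reductions and fold reductions of each parameter against the water
  control.

A synthetic generator produces isotherms with the same phase structure
(Volmer LE branch, optional coexistence plateau, constant-elasticity LC
branch, collapse clip, sigmoidal Δψ, Gaussian noise).  Its presets encode
the published summary values for all 18 lipid × subphase conditions, so
every detector can be validated by parameter recovery.

## Worked example

```python
import monofilm as mf

# generate the DPPE-on-water condition with measurement noise
spec, psi = mf.preset_spec("DPPE", "water", seed=1)
iso = mf.generate_isotherm(spec, psi, metadata=mf.preset_metadata("DPPE", "water"))

fs = mf.extract_features(iso)
print(f"lift-off  {fs.liftoff_area:6.1f} A2/molecule")
print(f"collapse  {fs.collapse_pressure:6.1f} mN/m at {fs.collapse_area:.1f} A2")
print(f"max Cs-1  {fs.max_modulus:6.1f} mN/m")
print(f"Cs-1@30   {fs.modulus_at_reference:6.1f} mN/m ({fs.phase_label_at_reference})")
print(f"max dpsi  {fs.max_potential:6.1f} mV")
```

prints

```
lift-off    43.4 A2/molecule
collapse    57.9 mN/m at 33.5 A2
max Cs-1   240.3 mN/m
Cs-1@30    239.6 mN/m (liquid-condensed)
max dpsi   600.7 mV
```

— recovering the injected condition (lift-off 43 Å², collapse 58 mN/m,
K_LC 240 mN/m, Δψ 600 mV) within detector tolerance.  The condensed-state
film at 30 mN/m is classified from its modulus band.  Comparing a treated
film against its control:

```python
from monofilm.compare import fold_reduction
fold_reduction(240, 50, rounding="nearest_integer")   # -> 5.0  (carvacrol on DPPE)
```

The same pipeline runs from the shell:

```
monofilm simulate --preset DPPG:carvacrol --seed 1 --out dppg_carvacrol.csv
monofilm analyze dppg_carvacrol.csv --out features.json
monofilm compare --features features.json --parameter max_modulus --out comparisons.csv
```

Input files are plain CSV with headers
`area_A2_per_molecule,surface_pressure_mN_per_m[,surface_potential_mV]`
and an optional JSON metadata sidecar; see `monofilm.io`.

## Layout

```
src/monofilm/
  io.py         isotherm records, CSV dialects, metadata sidecars
  smoothing.py  adjacent averaging (centered window, symmetric edge shrink)
  synthetic.py  piecewise generator, equation-of-state backbones, presets
  features.py   modulus pipeline and phase-feature detectors
  compare.py    feature tables, fold/percent reductions vs water control
  cli.py        simulate / analyze / compare commands
docs/methods.md   model, assumptions, numerical choices, limitations
```
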