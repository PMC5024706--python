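# Methods

## System and models

An isolated beetroot (*Beta vulgaris*) root vacuole is idealized as a
sphere of volume `V` (cm³) bounded by the tonoplast, immersed in a perfusion
chamber whose osmolality `Ce(t)` changes gradually after a solution switch.
The state is `(V, M)`, with `M` the intravacuolar solute amount (mol).
Five hypotheses about what shapes the volume response are encoded as forced
ODE systems:

| model | free parameters | mechanism |
|-------|-----------------|-----------|
| W     | `Pf`            | osmotic water flux only |
| WNOV  | `Pf, Vb`        | water flux; part of the volume (`Vb`) is osmotically inactive |
| WME   | `Pf, ε*`        | water flux opposed by elastic pressure `ΔP = ε*(V−V0)` |
| WS    | `Pf, Ps`        | simultaneous water influx and solute efflux |
| WSNOV | `Pf, Ps, Vb`    | WS fluxes acting on the active volume `V−Vb` |

All models share the phenomenological law of osmosis,
`Jv = A·Pf·Vw·(C_in − Ce)` with `C_in = M/(V−Vb)`, `dV/dt = Jv`; the solute
models add `Js = −A·Ps·(C_in − Ce)`, `dM/dt = Js`. The WME driving force is
reduced by `ΔP/(R·T)`. Membrane-potential coupling and water–solute
interaction (reflection-coefficient) terms are deliberately absent: the
experimental preparation depolarizes the tonoplast and uses non-electrolyte
(mannitol) gradients.

Units are mol, cm, s, dyn throughout; osmolalities are supplied in
mOsmol/Kgw and converted at 1 mOsmol/Kgw = 1e-6 mol/cm³ (unit solution
density). Constants: `Vw = 18 cm³/mol`, `R = 8.31e7 dyn·cm/(K·mol)`,
`T = 293 K`.

### Forcing

The external osmolality holds an iso-osmotic plateau `C0 = 450 mOsmol/Kgw`
until the switch at `t = 300 s` and then follows the measured
single-exponential decay `B·e^(−t/t*) + Ce*` with `B = 731.5`,
`t* = 237.2 s`, `Ce* = 258.8 mOsmol/Kgw`, evaluated on global experiment
time. Evaluated at the switch the exponential slightly overshoots the
plateau (≈465), so the forcing is clamped to the interval spanned by `C0`
and `Ce*`; the clamp releases ≈18 s after the switch. A hyper-osmotic
variant (`Ce* = 660`) mirrors the hypo decay constant and sets the
amplitude so the curve passes through `C0` at the switch; these are
placeholders for a measured hyper-osmotic time course.

### Initial condition

Simulations start from the vacuole equilibrated with the iso-osmotic bath:
`V(0) = V0` and `M(0) = M0 = (V0 − Vb)·C0`, so the osmotically active
compartment sits exactly at `C0` and the pre-switch plateau is a true rest
state. For models without a dead volume this is the usual `M0 = V0·C0`;
writing `V0·C0` for the dead-volume models would make the vacuole swell
during the iso-osmotic plateau, which contradicts the experiment.

### Integration

Forward Euler with `dt = 0.1 s` (the step used in the original fitting
routine; halving it changes the final volume by < 1e-4 relative, and the
step-to-step differences scale first order, which is tested). Both state
updates share a single gradient evaluation, which makes the WS conservation
line `Ps·(V−V0) + Pf·Vw·(M−M0) = 0` exact per step — this line plus the
zero-flux condition yields the closed-form steady state

    Vf/V0 = (1 + k·C0) / (1 + k·Ce),   k = (Pf/Ps)·Vw,

used as an independent oracle against long-time integration and to build
the (Pf, Ps) parameter-space map without a million ODE runs (ten random
cells are spot-checked against brute-force integration at 1e-4 relative).
The kernel is JIT-compiled with numba when importable; a pure-Python
fallback runs the identical arithmetic.

## Fitting and model selection

The fitness is the unweighted sum of squared residuals between the observed
relative volume and the simulated `V/V0` at the observation times.
Optimization is bounded Nelder–Mead, multi-start (default 8 starts: bounds
centre plus uniform draws in the transformed space, seeded), followed by a
tighter Nelder–Mead polish. Positive scale parameters (`Pf`, `Ps`, elastic
modulus) are searched in log10; the dead-volume fraction linearly. Bounds:
`Pf ∈ [1e-5, 1e-1]`, `Ps ∈ [1e-6, 1e-2]` cm/s, `Vb/V0 ∈ [0, 0.999]`,
elastic modulus `V0·ε* ∈ [1e-4, 100] MPa` — two decades around all reported
beetroot values. Noiseless self-generated records are recovered to ~1e-10
relative for every model, far inside the 1% tolerance the tests assert.

Models are ranked by small-sample corrected Akaike score
`AICc = n·ln(SSR/n) + 2k + 2k(k+1)/(n−k−1)`, `k` = free parameters + 1 for
the error variance; ties go to the model with fewer parameters. A perfect
fit (SSR = 0) maps to −∞ and outranks everything, with the tie-break still
applying. Only the ranking is treated as meaningful, not absolute scores.

## Cross-condition (pH) analyses

Per condition, WS fits are summarized as mean ± SEM of `Pf`, `Ps`, the
per-record ratio `Pf/Ps` (mean of ratios — not ratio of means; the two
differ appreciably, see Limitations) and the final observed `Vf/V0`.
The ratio-versus-pH law `Pf/Ps = A·e^(−(pH−pH*)/pH') + (Pf/Ps)*` is fit by
unweighted nonlinear least squares with `pH* = 6.6` fixed (it is the most
acidic condition and is reported without uncertainty, implying it was not
fitted); SEM weighting is available by flag but is not the default — on the
reference table it moves the fit away from the published parameters.
`Vf/V0` versus `Pf/Ps` is ordinary least squares. Both report asymptotic
95% intervals (t-based).

## Synthetic data

The generator emulates what the microscopy pipeline measures: a ground
truth trajectory is simulated, sampled every 30 s for 600 s from the
switch, converted to diameter, optionally quantized to the pixel grid,
perturbed with Gaussian diameter noise (default sd 0.5 μm) and converted
back to relative volume normalized by the first observation. Defaults:
pixel scale 3.24 μm/pixel (midpoint of the printed calibration range)
with quantization **off** (`pixel_scale = 0` semantics available): taking
the pixel scale as a hard quantization of a ~40 μm diameter would produce
volume staircases with ~25% jumps, which is incompatible with the
per-record scatter actually reported (steady-volume SEMs of 0.004–0.012)
— the acquisition software evidently measured diameters with sub-pixel
precision. Test cohorts therefore use sub-pixel Gaussian diameter noise of
0.1 μm (≈0.0075 relative-volume sd, the scatter scale the reported SEMs
imply).

Cohorts sample per-record `Pf` and the ratio `Pf/Ps` from unit-mean
log-normals (`Ps` derived), because reported per-vacuole ratios scatter far
less (cv ≈ 0.1–0.4) than independent `Pf`, `Ps` draws would produce
(cv ≈ 1.3): the two permeabilities are strongly correlated per vacuole.
Per-record seeds spawn deterministically from the cohort seed
(`numpy.random.SeedSequence`), and the manifest retains the ground truth
for recovery tests.

What passing tests show — and do not show: the generator reproduces the
sampling grid, the diameter-derived noise structure and the cohort-level
parameter spread of the real experiments, so pipeline closure (generate →
fit → summarize recovers the generating means) validates the estimation
machinery. It does not certify behaviour under image-segmentation
artifacts, drift, or non-spherical vacuoles, which the generator does not
emulate.

## Problem sizes

Default test and acceptance runs use: Euler step 0.1 s over 900 s (9001
grid points), 21 observations per record, 8 fit starts (4 in Monte-Carlo
sweeps), 50 model-selection replicates, 500 replicates for the
noise-propagation check, and spot checks of 10 cells on parameter-space
maps; the full map for the steady-volume figure is 1000 × 1000 cells via
the closed form.

## Known limitations

* **WS vs WME/WNOV discrimination.** On this protocol (30-s sampling,
  ~4–7% total swelling) the WME and WNOV families can mimic a WS record
  almost exactly: the best WME fit to a noiseless WS record leaves a
  structural SSR of only ~2e-7 (≈1e-4 relative volume per point), and WNOV
  ~9e-5. At any realistic measurement noise these gaps are far below the
  noise floor, so per-record AICc cannot reliably rank WS above WME — in
  simulation WME is in fact preferred slightly more often, because its
  parameterization flexes marginally more at equal parameter count. Once
  membrane relaxation is faster than the 30-s sampling interval the rate
  information also disappears, leaving `Pf` and `Ps` identifiable mainly
  through their ratio (consistent with the large reported `Pf` SEMs).
  Reliable WS selection on synthetic data requires a near-noiseless record;
  the corresponding model-selection test documents this honestly rather
  than passing under unrealistic conditions. Discrimination against W is
  robust (structural misfit ~2e-3), and WSNOV loses on the AICc parameter
  penalty.
* **Ratio-of-means vs mean-of-ratios.** The reference table's mean ratio
  per condition (e.g. 8.19 at pH 6.8) differs from the ratio of its mean
  permeabilities (7/1.4 = 5). The steady volume is a function of the ratio
  alone, so simulations at mean `Pf` and mean `Ps` undershoot the recorded
  steady volume at pH 6.8 (1.015 vs 1.023 ± 0.004) while the paired mean
  ratio reproduces it (1.025); both conventions land inside the SEM at
  pH 7.0 and 7.6.
* The hyper-osmotic forcing parameters are constructed, not measured.
* Absolute solute mass flows (particles/s) scale with the unreported
  vacuole surface area; a reporting utility exists but no numeric check is
  enforced.
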