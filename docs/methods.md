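# Methods

## The molar-balance model

The package quantifies the backend of vitamin D metabolism. The active
hormone 1,25(OH)₂D₃ (`m1`) is made intracellularly from the precursor
25(OH)D₃ (`m0`) by CYP27B1; CYP24A1 catabolizes both the hormone and
precursor that is diverted away from hormone synthesis. Catabolism ends in
five stable terminal metabolites: `m8`–`m10` (calcitroic acid,
calcitriol-26,23-lactone, calcioic acid) from the hormone and `m6`–`m7`
(cholacalcioic acid, 25(OH)D₃-26,23-lactone) from diverted precursor. The
central accounting identity is that hormone synthesized over an interval
equals hormone-end-metabolite synthesis over the same interval, which
equals the change in their total body amount plus their cumulative
excretion.

Assumptions, as implemented:

1. **Constant compartment volumes.** Extracellular volume `Ve` (plasma `Vp`
   a sub-space of it) and intracellular volume `Vi` are constants over the
   measurement interval.
2. **`Vi = 2·Ve`** (exact in both shipped presets).
3. **Gradient export.** Intracellular end-metabolite concentration is β
   times the extracellular one, β ≥ 1; default β = 1.1, exposed as a
   parameter since it is an initial setting rather than a measured value.
   A single β is shared by all five end metabolites — nothing in the model
   distinguishes them, and per-metabolite gradients would add parameters no
   assay currently constrains.
4. **Homogeneous extracellular concentrations**, so a plasma measurement
   stands for the whole extracellular space.
5. **Steady-state end accounting.** Intermediate catabolites (`m2`–`m5`)
   are assumed negligible relative to end metabolites. The
   `intermediate_buildup_check` compares a direct end-metabolite assay with
   a CYP24A1-driven one and reports the relative shortfall; when it exceeds
   the tolerance (default 10%) a correction is flagged rather than silently
   applied.
6. **Urinary share.** A fraction *f* of end-metabolite excretion leaves via
   urine; stool is never measured and always inferred as `(1−f)/f` times
   the urinary amount. Default *f* = 0.25; the excretion multiplier is
   written `1/f` (not a hard-coded 4) so the alternative published splits
   (32/68, 22/78) can be explored.
7. **Precursor correction.** In a driven diverted-end assay, circulating
   precursor in the sample is itself converted; `apply_precursor_correction`
   subtracts the serum `m0` amount, flooring at zero with an explicit flag
   (a negative difference indicates assay inconsistency, not physiology).

With these, the total body amount of a pool with summed extracellular
concentration `C` is `M = β·C·2Ve + C·Ve = C·Ve·(2β+1)`, and cumulative
synthesis over `(t₀, t₁)` is `Ve·(2β+1)·ΔC + (1/f)·C_u·V_u`.

### Parameters

| parameter | units | male preset | female preset | meaning |
|---|---|---|---|---|
| `Vp` | L | 3.0 | 2.5 | plasma volume |
| `Ve` | L | 14 | 11 | extracellular volume (incl. plasma and transcellular) |
| `Vi` | L | 28 | 22 | intracellular volume (= 2·Ve) |
| `beta` | — | 1.1 | 1.1 | intracellular/extracellular end-metabolite ratio |
| `urine_fraction` | — | 0.25 | 0.25 | urinary share *f* of total excretion |

The quoted female coefficient `4.4·Vp` equals the stored `Ve = 11 L`
exactly. The male `Ve/Vp = 14/3 = 4.6667` is conventionally quoted
truncated as 4.66; the estimators use the stored volumes (coefficient
`Ve·(2β+1) = 44.8`), not the rounded literal — propagating a display
rounding into estimates would introduce a spurious 0.14% bias — while
`volume_consistency_report` truncates to two decimals to reproduce the
quoted constant. The transcellular volume (0.4/0.5 L) is included inside
`Ve`, as the preset totals are.

### Conventions and degenerate inputs

- Canonical units everywhere: nmol/L, nmol, litres, hours. Mass↔molar
  conversion (exact, per-metabolite molar mass; or the ×2.5 rule of thumb
  for `m0` only) happens only at I/O boundaries. CSV readers require an
  explicit unit column — no unit is ever guessed.
- Estimates are accepted over any interval but labelled `per_24h` only when
  `t₁ − t₀ = 24 ± 0.5 h`.
- Negative synthesis totals are returned flagged, never clamped: they are
  diagnostic of an assumption violation (falling levels faster than
  excretion replaces them, or intermediate build-up).
- Undefined ratios are an explicit `None` plus a reason code
  (`diverted_pool_zero`: utilization is still 100%; `no_end_metabolites`:
  nothing is defined), never an infinity or a silent zero.
- The demand ratio reduces to a concentration-sum ratio because the
  `Ve·(2β+1)` factor cancels; the absolute `M₈:₁₀` is still reported as the
  point-in-time proxy for recent hormone synthesis.

## The forward simulator

Each end metabolite evolves independently (the system is linear) under

```
dA_i/dt = S(t) − k_t·(A_i/Vi − A_e/Ve)
dA_e/dt = k_t·(A_i/Vi − A_e/Ve) − k_x·A_e
dU/dt   = f·k_x·A_e          dF/dt = (1−f)·k_x·A_e
```

with piecewise-constant synthesis `S(t)` (nmol/h), transport coefficient
`k_t` (L/h) and extracellular clearance `k_x` (1/h), from a zero initial
state. At steady state `C_i/C_e = 1 + k_x·Ve/k_t`; `rates_for_beta` inverts
this to the unique `k_t = k_x·Ve/(β−1)` making the simulated gradient match
the estimators' β, so steady-state data satisfy the inverse model exactly.

Defaults are modelling choices, not measured values (no kinetic constants
exist for these metabolites): `k_x = 0.1/h` (a plausible ~10 h clearance
timescale), `k_t` from β. Baseline synthesis puts 0.1 nmol/h into the
hormone ends (2.4 nmol/day, consistent with ordinary daily calcitriol
turnover of roughly 1 µg) split 0.040/0.035/0.025 across `m8`/`m9`/`m10`,
and 0.1 nmol/h into the diverted ends (0.060/0.040 across `m6`/`m7`) — a
resting demand ratio of 1 and 50% utilization. Scenarios: `baseline`;
`infection_surge` (hormone-end synthesis ×4 between 48 h and 96 h, then
reverting); `pregnancy_sustained` (hormone-end synthesis ×4 throughout).

A caution on relaxation timescales: although extracellular clearance is
`k_x`, the pooled intra+extracellular amount relaxes at `k_x/(2β+1)` (time
constant 32 h at defaults) because the intracellular pool, 2β/(2β+1) of the
total, drains through the extracellular one. Post-surge return to within 1%
of baseline therefore takes ~10·(2β+1)/k_x ≈ 320 h, not 10/k_x.

### Numerics

Classical fixed-step 4th-order Runge–Kutta, default step 0.01 h. The system
is linear and non-stiff at default rates (fastest mode ≈ `k_t/Ve + k_x` ≈
1.1/h), so adaptive stepping buys nothing and a fixed step keeps runs
exactly bit-reproducible. Steps outside the RK4 stability region of the
fastest mode are rejected with a suggested maximum. Cumulative synthesis is
integrated as an extra state with the same scheme, which makes the mass
balance `∫S dt = A_i + A_e + U + F` an exact linear identity of the update
(observed residual ~1e-13) rather than a quadrature comparison; likewise
`U/(U+F) = f` holds exactly whenever anything has been excreted. Halving
the step changes 24-h cumulative amounts by well under 1e-6 relative.
Synthesis schedules are evaluated on the half-step grid, so rate
discontinuities aligned to the grid (as all scenario presets are) do not
degrade the integration.

### Sampling and noise

`sample_measurements` turns a trajectory into study measurements: serum
panels at requested times and a urine collection reported as amount over a
configurable collection volume (default 1.5 L, a mid-range normal 24-h
volume). Two serum conventions exist: `beta_consistent` (default) reports
the effective concentration `(A_i+A_e)/(Ve·(2β+1))` whose implied body
amount is exact — data that satisfy the estimators' β assumption
identically, the right convention for validating the balance algebra — and
`extracellular` reports the raw `C_e` an assay would see, which matches the
β assumption only at steady state. Measurement noise is multiplicative
lognormal with a given coefficient of variation (concentrations are
positive and assay error is relative), mean-preserving, and requires a
seed.

### What the synthetic data do and do not emulate

The simulator reproduces the model's own topology: linear kinetics, a
single homogeneous extracellular pool, constant volumes, no intermediate
metabolites, no protein binding, no renal impairment, no diurnal rhythm in
clearance. Passing recovery tests therefore demonstrates that the inverse
algebra is correct and robust to assay-level noise — not that the model is
an accurate description of human physiology. In particular, real assays
measure `C_e`, and off steady state the β assumption biases the body-change
term; the transient-recovery test quantifies that approximation error
within the model world only.

## Validation summary (computed by the test suite / acceptance script)

- Preset constants: female `Ve/Vp` 4.4, male 4.66 (truncated), `Vi/Ve` 2,
  male/female contrasts 20%/27%/127%, excretion multiplier 4, mass→molar
  factor 2.5.
- Pregnancy fixture: hormone fold-rise 336.3/85.6 ≈ 3.93 (rounds to 4) at
  near-constant precursor.
- Estimator ≡ simulator bookkeeping (β-consistent sampling, any interval,
  including transients) to 1e-6 relative.
- Steady-state recovery of ∫S dt: noiseless < 1%; with 10% assay CV,
  median absolute relative error ≈ 9% over 200 replicates.
- Simulator physics: mass conservation ≤ 1e-6 at every grid point,
  steady-state gradient ratio within 1e-4 of closed form, urinary share
  exactly *f*.

Problem sizes: validation runs use 240 h at step 0.02–0.05 h (4 800–12 000
steps), long enough for ≥ 7 slow-mode time constants of equilibration; the
Monte-Carlo uses 200 replicates.

## Limitations

- The fixtures' pregnancy studies measured `m2` (an initial intermediate),
  not the terminal `m6:7` the demand ratio requires, so they support the
  uncoupling illustration and directional comparisons only.
- No anthropometric scaling of volumes (weight/height); only the two
  presets plus custom entry.
- No vitamin D₂ species, C-3 epimers, protein-bound/free fractionation, or
  frontend synthesis (UVB, diet, hepatic 25-hydroxylation).
- The estimators inherit every model assumption; swelling, renal failure or
  large intermediate pools require the correction hooks, not the plain
  formulas.
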