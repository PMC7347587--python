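# Methods

## Models

### Log-time survival law

The population-level model treats the death rate as proportional to the
activation energy delivered per unit time, `dN/dt = Φμ·Ea/t`, whose
integral from the unitary time `t = 1 s` is

    N(t)  = k ln t,      N₁(t) = N₀ − k ln t,      k = Φμ·Ea,

with `Ea = n₀hc/λ` the energy of one einstein (mole of photons) and Φμ the
cell quantum mortality yield in mol/(erg·s). The law is dimensionally
informal: `ln t` acts on the numeric value of time in seconds, so `t = 1 s`
gives zero mortality by construction. We freeze that operational
convention because it is exactly how survival-count data are fitted
(survivors against `ln t`), and document rather than repair it. The
exponent `N₀/2k` of the half-population time likewise mixes a count with a
rate and is treated as the pure number it is in practice.

Characteristic times: `LDR₅₀ = exp(N₀/2k)` (survivors equal dead),
`tᵤ = 1/k` (minimum mortality time, one cell killed), `T = exp(N₀/k)`
(survivors reach zero), with the identity `T = LDR₅₀²`. Because `N₀/k` can
overflow `exp` for unphysical test parameters, both times are computed in
log space; when the linear-scale value is not representable the functions
warn and return `inf`, and the always-finite `log_ldr50`/
`log_absolute_death_time` carry the information.

Beyond `T` the raw law goes negative. The default curve evaluator clamps
survivors at 0 and dead cells at `N₀` and flags the affected grid points;
an unclamped mode preserves raw values, which is what the regression uses.
Times in (0, 1) are allowed (raw mortality negative) and flagged as the
pre-unitary regime; measurements never probe below 30 s.

### Collision (corpuscular) model

The genome is a homogeneous slab: volume `V_G`, thickness `Δx`, area
`A_G = V_G/Δx`, containing `N* = 2N_j/V_G` bases per cm³ (both strands of
`N_j` base pairs), each base presenting an effective impact section σ to a
photon travelling at `c`. Standard kinetic-theory quantities follow:

| quantity | formula | default value |
|---|---|---|
| macroscopic section Z | `N*σ` | 1.1806·10⁴ cm⁻¹ |
| mean free path l̄ | `1/Z` | 8.470·10⁻⁵ cm |
| excitation time Δtᵢ | `1/(N*σc)` | 2.8253·10⁻¹⁵ s |
| impact frequency f | `N*σc` | 3.5394·10¹⁴ s⁻¹ |
| absorbed fraction δ | `N*σΔx = ZΔx` | 0.6507 |

δ is implemented as the *expected number of impacts per traversal*
(linear in Δx), which is the convention behind the published value 0.6506;
the saturating Beer–Lambert probability `1 − exp(−ZΔx)` is exposed
separately (`absorbed_probability_beer_lambert`) for comparison only. The
three algebraically equivalent forms `N*σΔx`, `2N_jσ/A_G` and `Δx/l̄` are
kept as tested identities.

The lethal impact number `f(tᵤ) = N*σc/k` counts photon impacts
accumulated over the minimum mortality time and closes the loop to the
population law: substituting `k = N*σc/f(tᵤ)` reproduces the log-time
curves exactly (tested pointwise to 1e-12). Under the proportionality
hypothesis `f(tᵤ) ≈ N_j`, the rate becomes genome-geometric:

    k̄ = 2σc/V_G ≈ 6.8065·10⁷ s⁻¹
    t̄ᵤ = 1/k̄ ≈ 1.4691·10⁻⁸ s
    Φ̄μ = 2σλ/(V_G·n₀h) ≈ 1.4435·10⁻⁵ mol/(erg·s)

and the two model families agree through `Φ̄μ·Ea = k̄`.

### Photons per dimer

`D_p = 1/Φμ` is the photon budget per pyrimidine dimer, carried in the
yield's own numeric convention (the reciprocal of a mol/(erg·s) value read
as a pure number) — the convention in which the published strain table is
written; no unit reconciliation is attempted. Every (coefficient, D_p)
pair satisfies `coefficient × D_p = n₀hV_G/(2σλ) ≈ 6.9275·10⁴`, and all
rows are completed with the 253.7 nm constant even where the source
experiment quotes 254 or 260 nm: only the single-wavelength constant
reproduces every published D_p from its coefficient, so the quoted
wavelength column is treated as annotation. D_p ≫ 1 across the whole panel
is the multi-impact signature.

## Constants and units

Everything is CGS (erg, cm, s): n₀ = 6.0225·10²³ mol⁻¹,
h = 6.6256·10⁻²⁷ erg·s, c = 2.9979·10¹⁰ cm/s, λ = 2.537·10⁻⁵ cm, and for
the mean *E. coli* genome N_j = 5.2·10⁶ bp, V_G = 4.3716·10⁻¹³ cm³,
Δx = 5.5111·10⁻⁵ cm, σ = 4.9627·10⁻¹⁶ cm². These 4–5-significant-figure
values are canonical for the package; they are deliberately not updated to
CODATA precision, because every derived constant above is validated
against numbers printed from them. Constants are frozen dataclasses;
overrides go through the YAML configuration (`constants.*`, `genome.*`),
never mutation. A wavelength outside the UV-C band (200–280 nm) warns but
does not fail, since the formulas remain meaningful for germicidal
neighbours. Energy bookkeeping is per mole of photons (einsteins);
per-photon energy `hc/λ` is a separate accessor.

## Estimation

`fit_survival` regresses pooled survivor counts on `ln t` by OLS
(statsmodels). Conventions:

* `t = 0` control rows set `N₀` (absolute mode) or the 100 % level
  (normalized mode) and are excluded from the regression — `ln 0` is
  undefined.
* **Detection limit.** A plate with zero colonies means the survivor
  concentration fell below `1/(dilution·volume)`, not that survivors were
  observed to be zero; such records are censored out of the fit by default
  (`exclude_below_detection=False` restores them). Without this policy,
  fast-dying populations whose absolute-death time falls inside the
  sampling window would bias the slope toward zero by up to ~70 %.
* At least three distinct positive exposure times must remain.
* "Fiducial limits" are individual-observation prediction intervals and
  "confidence intervals" are mean-response bands, both at 0.97 by default
  (matching the 0.03 significance convention of the t test); the two-band
  report mirrors how survival dispersion plots are drawn.
* `k̂ = |slope|`, `Φ̂μ = k̂λ/(n₀hc)`. The absolute scale of `Φ̂μ` depends on
  the count unit fitted (absolute counts vs percent of control); the fit
  records which mode was used. R² is invariant under count rescaling.
* Strain-level comparison to theory is a one-sample t test of the fitted
  rates against `k̄` at α = 0.03. A zero-variance sample of estimates is
  handled as the analytic limit (t = 0, p = 1 when the mean equals the
  reference). No multiple-testing correction is applied across strains.

On noiseless model data the fit recovers `k` and `N₀` to machine
precision; under the default Poisson plating noise, 200 simulate-and-refit
runs with k uniform over the experimentally observed 2–7·10⁷ s⁻¹ range
give a median relative error of ~3 % and 0.97-CI coverage of ~0.96.

## Synthetic data generator

The generator emulates the plating experiment: 3 ml of ~10⁸ cells/ml
culture per dish (`N₀ = 3·10⁸`), exposures 30–300 s in 30 s steps,
triplicate experiments, five-step decimal serial dilution, and a colony
count at the dilution whose expected count lies in the standard 30–300
countable window (falling back to the closest achievable count when no
dilution qualifies, e.g. undiluted controls). Counts are Poisson; an
optional lognormal multiplier on the Poisson mean
(`poisson_lognormal`, σ configurable) emulates between-plate
overdispersion for robustness studies. `plated_volume_ml = 3.0` scales
CFU/ml concentrations back to dish populations so that the deterministic
mode is the exact algebraic inverse of `counts_to_survivors`. Fluence
(2.75 mJ/(s·cm²) × t) is recorded per row as metadata only; the kinetics
are parameterised by time. A mandatory integer seed makes every dataset
byte-reproducible.

What the generator does *not* emulate: lamp/irradiance geometry, repair
kinetics (photoreactivation, NER/SOS) and their dose-rate effects,
non-Poisson colony-counting errors (merging, counting fatigue), pipetting
bias across the dilution series, and strain-to-strain genome differences.
Passing recovery tests therefore shows the estimator is correct *under the
model's own assumptions*, not that real strains obey the log-time law.

The Monte Carlo impact oracle samples exponential free paths at rate Z and
Poisson impact counts with mean δ per traversal — a statistical check of
the analytic means at the 1/√n rate, not a photon-transport engine
(elastic scattering and target depletion are ignored, matching the
analytic model's assumptions).

## Numerical choices

* All reciprocal/product identities (l̄Z = 1, fΔtᵢ = 1, ktᵤ = 1, the
  unitary mortality identity) are maintained and tested at 1e-12 relative.
* `k` is always derived as `Φμ·Ea`; the two are never stored separately,
  eliminating inconsistent states.
* Degenerate regression designs (fewer than three distinct times, all
  counts at one time) raise; a negative fitted `N₀` warns and is flagged
  rather than rejected.
* Simulation child seeds are spawned from a `SeedSequence` and reduced
  below 2³¹ so datasets remain portable across platforms.

## Problem sizes

Default study sizes — 10⁵ photons for the Monte Carlo oracle, 200
simulate-and-refit runs for recovery summaries, 50+ simulations per design
in `recovery_study` — were chosen so Monte Carlo standard errors are
comfortably below the effects being measured (3-SE acceptance margins)
while a full run stays in the seconds range.

## Known limitations

* The log-time law has no explicit dose-rate or repair term; Φμ absorbs
  repair capacity implicitly, which is why it varies between
  repair-proficient and -deficient strains.
* σ is consumed as a constant (no wavelength-dependent action spectrum,
  no TT/TC/CC site resolution).
* The published experimental statistics (per-strain R, R², p-values)
  cannot be recomputed without the raw plate counts, which are not
  published; the package instead validates the estimation pipeline by
  simulation at the same design.
* Published dose bookkeeping is internally inconsistent by a factor of ten
  (83–830 mJ/cm² fluence vs a quoted 0.627–6.27 J/dish over 75.42 cm²);
  the generator records fluence per cm² only.
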