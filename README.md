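# uvkin

Kinetics of UV-C germicidal inactivation of *E. coli*, modelled at the
photon–DNA level.

Low-pressure mercury lamps (253.7 nm) kill bacteria by driving pyrimidine
dimer formation in the genome. `uvkin` implements two coupled descriptions
of this process and the statistics needed to confront them with plate-count
data:

* **A log-time survival law.** Mortality accumulates as
  `N(t) = k ln t`, survivors as `N₁(t) = N₀ − k ln t`, where the *specific
  speed of mortality* `k = Φμ·Ea` couples the *cell quantum mortality
  yield* Φμ (dead cells per absorbed einstein per unit time) to the
  activation energy `Ea = n₀hc/λ` of a mole of photons. Characteristic
  times follow in closed form: the half-population exposure
  `LDR₅₀ = exp(N₀/2k)`, the minimum mortality time `tᵤ = 1/k`, and the
  absolute-death time `T = exp(N₀/k)`.

* **A corpuscular collision model.** The genome is a slab of volume `V_G`
  and thickness `Δx` holding `N* = 2N_j/V_G` bases per cm³, each with an
  effective impact cross-section σ. Kinetic theory gives the macroscopic
  section `Z = N*σ`, mean free path `l̄ = 1/Z`, excitation time
  `Δtᵢ = 1/(N*σc)`, impact frequency `f = N*σc` and the expected impacts
  per traversal `δ = ZΔx`. The *lethal impact number* `f(tᵤ) = N*σc/k`
  links collisions to mortality; assuming it is proportional to the
  base-pair count `N_j` yields parameter-free predictions
  `k̄ ≈ 2σc/V_G`, `t̄ᵤ = 1/k̄` and `Φ̄μ ≈ 2σλ/(V_G n₀ h)`.

* **Estimation and simulation.** Ordinary least squares of survivor counts
  on `ln t` recovers `k̂`, `N̂₀` and `Φ̂μ` with correlation/determination
  coefficients, 0.97 mean-response and individual-observation (fiducial)
  bands, and a one-sample t test against the theoretical rate. A synthetic
  generator emulates the plating experiment (3 ml dishes at ~10⁸ cells/ml,
  30–300 s exposures in 30 s steps, five-step decimal serial dilution,
  Poisson colony counts in the 30–300 countable window, triplicates) so
  the whole pipeline is testable without laboratory data.

* **Photons-per-dimer bookkeeping.** The reciprocal yield `D_p = 1/Φμ`
  counts photons needed per pyrimidine dimer; the proportionality
  coefficient `Φμ·n₀hV_G/(2σλ)` measures how close a strain sits to the
  theoretical mean. `D_p ≫ 1` throughout the published strain panel —
  multi-impact kinetics, not single-hit Chick–Watson behaviour.

## Worked example

The theory table for the default *E. coli* genome (5.2 Mbp,
V_G = 4.3716·10⁻¹³ cm³, σ = 4.9627·10⁻¹⁶ cm²):

```sh
$ uvkin theory
{
  "n_star_per_cm3": 2.378991673529143e+19,
  "mean_free_path_cm": 8.470110098256067e-05,
  "excitation_time_s": 2.825347776195359e-15,
  "impact_frequency_per_s": 353938728685149.6,
  "absorbed_fraction": 0.650652699441852,
  "ems_z_per_cm": 11806.221978223077,
  "k_bar_per_s": 68065140.13175954,
  "tu_bar_s": 1.4691808436215867e-08,
  "phi_mu_bar_mol_per_erg_s": 1.4435307719689671e-05
}
```

Read: a 253.7 nm photon entering the genome slab suffers on average 0.65
absorptions per traversal (≈35 % of the genome is never hit), bases are
excited for ~2.8 fs between impacts, and a culture should lose cells at
k̄ ≈ 6.8·10⁷ per ln-second, i.e. one cell killed after t̄ᵤ ≈ 15 ns of
cumulative photochemistry.

Simulate a plated exposure series at k = 5·10⁷, N₀ = 3·10⁸ and refit it:

```sh
$ uvkin simulate --k 5e7 --n0 3e8 --seed 42 -o demo.csv
$ uvkin fit demo.csv
{
  "synthetic": {
    "k_hat": 49388350.08,
    "n0_hat": 296517728.58,
    "phi_mu_hat": 1.0474e-05,
    "R": -0.9948,
    "R2": 0.9897,
    "k_ci": [47208922.91, 51567777.25],
    "mmt_s": 2.0248e-08,
    "ldr50_s": 20.12,
    ...
  }
}
```

The fitted rate lands within 1.3 % of the simulated truth and the 0.97
confidence interval covers it; R² ≈ 0.99 matches the goodness of fit seen
in real survival curves of repair-competent strains.

Other subcommands: `uvkin predict --k 5e7 --n0 3e8` tabulates the model
curves with LDR₅₀/tᵤ/T, and `uvkin hypothesis --coefficient 1.0613`
completes a photons-per-dimer row (→ D_p ≈ 65 274).

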