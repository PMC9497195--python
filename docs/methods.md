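# Methods

## Model

`ddaflux` resolves the daily carbon and nitrogen economy of one
diatom–diazotroph association (DDA) under the steady-state assumption:
every elemental pool's supply equals its consumption, with no waste, so
that all fixed C and N go to growth, respiration and the cost of N₂
fixation. The association comprises one diatom host and `n_trichomes`
cyanobacterial filaments, each of `vegetative_per_trichome`
photosynthesising cells and `heterocysts_per_trichome` heterocysts.
Heterocysts fix N₂ but no carbon; the diatom and vegetative cells
photosynthesise but never fix N₂; all compartments grow at the same rate µ.

The two balances per association and day are

* carbon: `F_pho,D + F_pho,V = µ·(Q_C,V(1+E_V) + Q_C,H(1+E_H) + Q_C,D(1+E_D)) + F_C,fix`
* nitrogen: `F_N,fix + V_NH4 = µ·(Q_N,V + Q_N,H + Q_N,D)`

Ammonium uptake is performed by the diatom and follows Monod kinetics in
the ambient concentration, with maximum rate proportional to the diatom's
carbon quota. Fixation takes up the nitrogen demand that uptake leaves
uncovered and is floored at zero; when Monod uptake would exceed
whole-association demand, effective uptake is clipped to demand (a
steady state admits no nitrogen waste — both potential and effective
uptake are reported). Fixation costs carbon at `f_CN` pmol C per pmol N,
added to the photosynthesis requirement outside the `(1+E)` respiration
factor. Total photosynthesis is split between diatom and vegetative cells
in proportion to their nitrogen quotas.

Transfers are diagnostic quantities of the same solution:

* `tc = µ·(Q_C,V(1+E_V)+Q_C,H(1+E_H)) + F_C,fix − F_pho,V` — carbon the
  trichomes need beyond their own photosynthesis; positive diatom→trichome
  in every scenario explored.
* `tn = µ·Q_N,D − V_NH4,eff` — nitrogen the diatom needs beyond its own
  uptake; positive trichome→diatom, crossing zero at the closed-form
  no-transfer concentration `K_m·a/(1−a)` with `a = µ/(r_CN·v_max)` and
  turning negative (excess ammonium pushed to the trichomes) above it.
  The analogous closed form with whole-association demand gives the
  zero-fixation concentration. Because fixation happens in heterocysts,
  budgets report `tn` as the heterocyst→diatom leg and expose the
  within-trichome heterocyst→vegetative leg separately, so either
  accounting of the trichome-internal arrow is recoverable.

Percentage budgets use one base — total supply, which at steady state
equals total consumption — for both sides of each element, so supply
shares and consumption shares each sum to 100 exactly.

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| cell volumes D/V/H | 3493.5 / 18.8 / 61.0 | µm³ | typical observed values |
| cell ratios | 1 diatom : 2 trichomes; 4 vegetative : 1 heterocyst | — | *Hemiaulus–Richelia* observations |
| allometry, diatom | log₁₀ pgC = −0.933 + 0.881·log₁₀V | — | large-diatom regression |
| allometry, cyanobacteria | log₁₀ pgC = −0.665 + 0.939·log₁₀V | — | protist regression |
| r_CN | 6.6 | mol C / mol N | Redfield ratio |
| E (all compartments) | 0.38 | — | respiration : biosynthesis |
| v_max | 1.16 | pmol N (pmol C)⁻¹ d⁻¹ | diatom ammonium-uptake modelling |
| K_m | 0.483 | mmol m⁻³ | same source |
| f_CN (fixation C cost) | 2.07 | pmol C (pmol N)⁻¹ | calibrated, see below |
| µ validated band | 0.3–0.8 | d⁻¹ | culture observations (warns outside) |
| light: Pmax per N quota | 15 | pmol C (pmol N)⁻¹ d⁻¹ | package choice, see below |
| light: initial slope α | 0.3 | pmol C d⁻¹ (µmol photons m⁻² s⁻¹)⁻¹ | package choice |

The volume→carbon regression source offers several regressions without
stating which applies to which cell class here. The pairing above —
large-diatom curve for the host (its volume is far beyond the large-cell
breakpoint), protist curve for the small cyanobacterial cells — is the
combination under which the published no-transfer (0.034 mmol m⁻³) and
zero-fixation (0.036 mmol m⁻³) concentrations are reproduced, and it puts
the diatom's share of association carbon at 0.764; coefficients are
ordinary config keys.

`f_CN` is not printed in the sources; it is pinned by least squares so the
model reproduces the two published relative C-transfer values at
µ = 0.51 d⁻¹ (22.7 % of total C supply at zero ammonium, 11.1 % at
0.04 mmol m⁻³). The fit gives 2.0673 (the two single-anchor roots are
2.05 and 2.79); the frozen default is 2.07, re-derivable at any time via
`ddaflux.calibration.fit_fixation_cost` and overridable in config.

## Light mode

With an irradiance given, each photosynthesising compartment gets a
saturating capacity `Pmax_x·(1 − exp(−α·I/Pmax_x))`, `Pmax_x`
proportional to its N quota with one shared initial slope. Realised
photosynthesis keeps the quota-proportional split but is capped by
capacity, the shortfall reassigned to the unconstrained compartment;
scenarios whose total capacity cannot meet the required supply are
flagged infeasible, never silently truncated. Because at low light both
capacities approach `α·I` while the diatom must carry ~85 % of the
requirement, the diatom's cap binds first: rising irradiance raises its
realised photosynthesis and the net C transfer until the light-replete
solution is recovered, while all N-side fluxes (uptake, fixation, `tn`)
are independent of light. The defaults (Pmax = 15 pmol C pmol N⁻¹ d⁻¹,
α = 0.3) place saturation near 100–200 µmol photons m⁻² s⁻¹ and keep Pmax
above the light-replete requirement across µ ∈ [0.3, 0.8]; the exact
functional form and values are a package choice pinned only by this
qualitative contract, and both are config keys.

## Numerical choices

The model is closed-form; no iteration is involved. Balance residuals are
carried in every solution and required below 1e-9 relative tolerance;
threshold closed forms are cross-validated against bisection on the
transfer sign change to 1e-9. Degenerate inputs: µ = 0 yields zero fluxes
(and an undefined percentage budget, rejected with an error); demand
exceeding maximum uptake capacity makes the threshold concentrations
infinite and raises an error; uptake clipping keeps fixation non-negative
at super-saturating ammonium. CSV output carries 6 significant digits,
JSON full double precision; sweeps traverse the Cartesian grid row-major
in the listed axis order and are byte-deterministic. There is no
randomness anywhere in the pipeline.

## Sensitivity variants

`double_vegetative_E` doubles the vegetative respiration ratio to 0.76
(per-compartment E values exist for exactly this purpose; the printed
balance uses one shared E, to which the implementation collapses when all
three are equal). `half_vegetative_pmax` halves the vegetative
light-saturated photosynthesis rate and only matters in light mode. Both
leave every qualitative ordering of the default model intact (tested).

## What passing tests show — and what they do not

All quantitative checks run the model at the composition and parameter
defaults above; they establish internal consistency (exact mass balance,
normalised budgets, monotonicities, threshold agreement, scale invariance
under uniform quota rescaling) and agreement with the published model
outputs at the published scenario corners. They do not validate the model
against field or culture measurements: real DDAs experience diel cycles,
non-steady dynamics, nitrate and other N sources, and cell-to-cell
variability, all outside this model's scope by construction.

## Known limitations

* Steady state only; no ODE dynamics, no diel light cycle.
* Ammonium is the only external N source; no nitrate, no P/Si/Fe quotas.
* One global C:N ratio for all compartments.
* The light-response form and its two parameters are contract-compatible
  stand-ins, not fitted to photophysiology data.
* Absolute (per-association) N transfer is independent of trichome count
  by construction (diatom demand and diatom uptake do not depend on it);
  the published decrease with trichome number refers to the relative,
  percent-of-supply measure, which the model reproduces.
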