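# ddaflux

A coarse-grained, steady-state carbon/nitrogen flux model of
**diatom–diazotroph associations (DDAs)** — symbioses between a diatom host
(*Hemiaulus*-type) and filamentous N₂-fixing cyanobacteria (*Richelia*-type)
that dominate dinitrogen fixation in the oligotrophic ocean. The package is
for biological oceanographers and systems biologists who want to quantify
how ambient ammonium, growth rate, trichome number and light reshape the
metabolism of and nutrient exchange within the symbiosis.

## The model

Each elemental pool is assumed to be at steady state over a day, so supply
equals consumption per association:

```
C:  F_pho,D + F_pho,V = µ·(Q_C,V·(1+E_V) + Q_C,H·(1+E_H) + Q_C,D·(1+E_D)) + F_C,fix
N:  F_N,fix + V_NH4   = µ·(Q_N,V + Q_N,H + Q_N,D)
```

with growth rate µ (d⁻¹), pooled carbon/nitrogen quotas Q per compartment
(diatom D, vegetative cells V, heterocysts H), respiration-to-biosynthesis
ratios E (default 0.38), and a carbon price of fixation
`F_C,fix = F_N,fix · f_CN` (default f_CN = 2.07 pmol C pmol N⁻¹, calibrated
by least squares — see `ddaflux.calibration`). Ammonium uptake by the diatom
follows Monod kinetics scaled by the diatom carbon quota,

```
V_NH4 = v_max · Q_C,D · [NH4+] / ([NH4+] + K_m),   v_max = 1.16 pmol N (pmol C)⁻¹ d⁻¹,  K_m = 0.483 mmol m⁻³,
```

fixation covers the remaining N demand (floored at zero), and total
photosynthesis is split diatom : vegetative in proportion to N quotas.
Quotas come from cell volumes (3493.5 / 18.8 / 61.0 µm³ for
diatom / vegetative / heterocyst) through log-log volume-to-carbon
allometries and a Redfield C:N of 6.6. Net transfers follow from
per-compartment budgets: carbon consistently diatom→trichome, nitrogen
trichome→diatom at low ammonium and reversed above the closed-form
**no-transfer concentration** `K_m·a/(1−a)` with `a = µ/(r_CN·v_max)`.

## Worked example

Solve one scenario (growth 0.51 d⁻¹, ammonium 0.01 mmol m⁻³):

```sh
$ ddaflux solve --mu 0.51 --nh4 0.01
{
  "v_nh4": 0.30244375512963173,
  "fn_fix": 0.9978818151899156,
  "fc_fix_cost": 2.065615357443125,
  "s_pho_total": 13.908980651913561,
  "f_pho_d": 11.825738476646332,
  "f_pho_v": 2.0832421752672285,
  "tc": 2.779192095086353,
  "tn": 0.690809031602909,
  ...
}
```

Uptake supplies 0.30 pmol N d⁻¹ and fixation the remaining 1.00; fixation
costs 2.07 pmol C d⁻¹ on top of growth and respiration, so total
photosynthesis must reach 13.9 pmol C d⁻¹, 85% of it in the diatom. The
diatom exports 2.78 pmol C d⁻¹ (`tc` > 0, diatom→trichome, 20% of the C
supply) and receives 0.69 pmol N d⁻¹ of fixed nitrogen (`tn` > 0,
trichome→diatom). The percentage budget and the analytic thresholds:

```sh
$ ddaflux budget --mu 0.4 --nh4 0.01     # n_fixation 70.3%, c_transfer 19.2%
$ ddaflux thresholds --mu 0.51 --mu 0.4
mu,no_transfer_nh4,zero_fixation_nh4
0.51,0.034471,0.0461462
0.4,0.0266262,0.0354624
```

At µ = 0.51 d⁻¹ net N transfer vanishes at 0.034 mmol m⁻³ ammonium; at
µ = 0.4 d⁻¹ fixation shuts off entirely above 0.035 mmol m⁻³. Grid sweeps
over `nh4`, `mu`, `n_trichomes` and `irradiance` write CSV:

```sh
$ ddaflux sweep --mu 0.51 --axis nh4=0,0.01,0.02,0.03,0.04 --out sweep.csv
```

All defaults can be overridden with a YAML config (`--config model.yaml`;
run `ddaflux show-config` to see every key with its default).

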