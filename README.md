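# avipva

Stochastic Leslie-matrix assessment of bird mortality limits.

`avipva` builds postbreeding-census, female-based Leslie matrices from
vital-rate tables for seven bird species (eleven
species–population–period parameter sets ship with the package),
projects them with environmental stochasticity, and quantifies how three
mortality-limit rules affect population viability:

* **%-of-natural-mortality criteria** (e.g. the 1% derogation
  threshold): every age class's mortality is scaled by `1 + x` and the
  10-year population decline is measured against an untreated baseline.
* **Potential biological removal (PBR)**: the constant annual removal
  fraction `Fp = 0.5 · r0 · Fr` is applied to every age class of a
  density-dependent model and the responses of the low-density growth
  rate `r0` and the equilibrium density `N*` are measured. Both follow
  the `-Fr/2` law almost independently of species and growth rate.
* **A scalar allowable-mortality rule** `Fp ≈ r0 · R`: the kill fraction
  that keeps the equilibrium-density reduction near an acceptable `R`,
  validated against the full matrix models.

Density dependence acts on recruitment via the multiplier
`max(0, 1 − A/K′)`, where `A` is the breeding-probability-weighted adult
count and `K′` the adult count at which recruitment is zero;
recruitment is first calibrated so the low-density growth rate hits a
target `λ0 ∈ {1.01, 1.03, 1.1}`.

## Layout

| module | contents |
| --- | --- |
| `avipva.demography_io` | vital-rate data model, CSV schema, packaged fixtures (`data/vital_rates.csv`) |
| `avipva.leslie_model` | matrix construction, eigen-analysis, elasticity, mortality transform |
| `avipva.stochastic_engine` | seeded environmental-stochasticity projections, 10-year decline statistic |
| `avipva.density_dependence` | recruitment calibration, equilibrium density, response summaries |
| `avipva.pbr_harvest` | PBR quotas, harvested simulations, recovery-factor sweeps |
| `avipva.threshold_methods` | scalar allowable-mortality rule, mini-model vs matrix comparison |
| `avipva.synthetic_species` | random but valid life histories for testing |
| `avipva.cli_report` | experiment runners and the `avipva` command line |

## Command line

```sh
# density-independent projection of one fixture
avipva project --species "Common Starling" --period 1990-2012 \
    --extra-mortality 0.01 --reps 10000 --seed 42 --years 100

# density-dependent response of r0 and N* to extra mortality
avipva dd-response --species "Common Starling" --period 1960-1978 \
    --lambda0 1.1 --extra-mortality 0.10 --kprime 10000 --seed 7

# PBR recovery-factor sweep across all fixtures
avipva pbr-sweep --fr 0.1:1.0:0.1 --lambda0 1.01,1.03,1.1 --reps 200 --seed 11

# scalar allowable-mortality rule
avipva allowable --r0 0.1 --acceptable-decline 0.01   # -> 0.001

# mini-model vs matrix comparison (132 combinations)
avipva compare-minimodel --reps 200 --seed 3 --out comparison.csv

# synthetic life histories in the fixtures CSV schema
avipva synth --n 20 --seed 1 --out synth_rates.csv

# everything at once, with a run log
avipva report-all --out-dir results/ --seed 1
```

Every CSV the reporting commands write embeds the seed, the grids and
the package version as `#` header lines; re-running with the same
configuration is byte-identical.

## Notes on protocols

* Environmental stochasticity draws each vital rate independently every
  year from a normal distribution clipped to its valid range; paired
  scenarios reuse the same standard-normal deviates (common random
  numbers).
* Equilibrium density is measured in reproducing adults (the currency
  of the recruitment feedback and of `K′`) as the mean over a window of
  years after a long burn-in; a replicate whose total population drops
  below one individual is extinct and contributes zero. Near-critical
  scenarios approach equilibrium on a ~10³-year horizon, hence the long
  default burn-in for response grids.
* Desk-scale defaults (10⁴ replicates for density-independent runs,
  a few hundred for density-dependent grids) keep runs fast; all counts
  are configurable.
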