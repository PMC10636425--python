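# scr-camtrap

Bayesian spatial capture–recapture (SCR) density estimation for
camera-trap surveys of individually identifiable animals — built for the
kind of single-season Eurasian lynx monitoring run on systematic
camera-trap grids, where a handful of individuals are photographed a
handful of times each and population density must still be estimated
with honest uncertainty.

The package takes you from raw field tables (trap deployments with
per-day effort, photo-identification records) to realised-density
posteriors, convergence diagnostics, activity-centre density rasters
and minimum-convex-polygon (MCP) densities. A synthetic survey
generator with known truth makes every stage testable without any field
data.

## The model

Detections are modelled with the closed-population SCR model M0 under
Bayesian data augmentation. A super-population of *M* rows carries
latent inclusion indicators *z*ᵢ ~ Bernoulli(ψ) and activity centres
*s*ᵢ uniform over a rectangular state space *S* (the trap bounding box
buffered on all sides). Given *z*ᵢ = 1, individual *i* is detected at
trap *j* on a one-day occasion with half-normal probability

> p(i, j) = g₀ · exp(−‖sᵢ − xⱼ‖² / 2σ²)

masked by the per-site, per-day usage indicator (stolen or broken
cameras are zero effort from the loss date). Detection is constant
across individuals and occasions (M0): with at most one detection per
individual–site–day, per-site detections are Bernoulli products, which
the likelihood evaluates in exact Binomial form. Priors are vague:
g₀, ψ ~ U(0,1), σ ~ U(0, half the state-space side), sᵢ ~ U(S).

A Metropolis-within-Gibbs sampler (conjugate updates for *z* and ψ,
random-walk updates for *s*, g₀, σ with burn-in-only adaptation) yields
the realised population size N = Σzᵢ and realised density
D = N / |S| × 100 km² at every draw. Reported are the posterior mean of
D, its 95% highest-posterior-density (HPD) interval, and the
coefficient of variation (posterior SD / mean; ≤ 0.20 is conventionally
"high precision"). Convergence is declared when the 95% upper bound of
the Gelman–Rubin statistic is below 1.1 for every monitored parameter.
Realised activity centres are additionally summarised as a 1-km² raster
and as a density over the MCP of the trap array.

Before fitting, field records pass the standard identification rules:
unidentifiable events are dropped but counted, juveniles are merged
into their mothers where known, and individuals photographed on a
single flank only are discarded (configurable) to avoid double
counting. Survey tallies (recaptures, spatial recaptures, skewness of
recaptures, effective trap-nights) are reported alongside.

## Worked example

Simulate a reduced exclusion-zone-like survey (30 paired-camera sites
on a 2.5-km checkerboard grid, 60 daily occasions, true density
1.54/100 km², g₀ = 0.0025, σ = 4 km) and analyse it:

```python
import scr_camtrap as sc
from scr_camtrap import synthetic_data as syn

sim = syn.demo_config()                      # 30 traps, 60 occasions, M = 100
data = syn.simulate_survey(sim, seed=1)
config = syn.survey_config_for(sim, seed=1)  # 3 chains x 10,000, burn-in 2,000
result = sc.run_analysis(config, data.traps, data.detections, out_dir="scr_demo")

s = result.summary
print(f"individuals  : {s.n_individuals} ({s.total_recaptures} recaptures, "
      f"{s.spatial_recaptures} spatial)")
d = result.density
print(f"true density : {data.truth['density_per_100km2']:.2f} / 100 km2")
print(f"estimate     : {d.mean:.2f} (95% HPD {d.hpd_low:.2f}-{d.hpd_high:.2f}, CV {d.cv:.2f})")
print(f"MCP density  : {result.mcp.density_per_100km2:.2f} / 100 km2")
print(f"converged    : {result.converged}")
```

prints

```
individuals  : 8 (3 recaptures, 3 spatial)
true density : 1.53 / 100 km2
estimate     : 2.18 (95% HPD 0.47-4.60, CV 0.54)
MCP density  : 2.01 / 100 km2
converged    : True
```

Eight detected individuals with three recaptures is genuinely sparse
data, and the output reflects that: the truth (1.53) sits inside a wide
95% HPD, and the CV of 0.54 honestly signals low precision. `scr_demo/`
receives the full artifact set: `summary.json` (survey tallies),
`estimates.json`, `diagnostics.json` (R-hat table), per-chain CSVs,
thinned activity centres, `mcp.geojson` and the `raster.asc` ESRI ASCII
density grid.

The same pipeline is available from the shell:

```sh
scr-camtrap simulate --preset ucez --seed 1 --out survey/
scr-camtrap summarize --config survey/config.yaml --traps survey/traps.csv --detections survey/detections.csv
scr-camtrap run --config survey/config.yaml --traps survey/traps.csv --detections survey/detections.csv --out survey/out
```

Presets `sbnp`, `ucez` and `bpp` mirror the layouts of three lynx
study areas (35/65/50 sites, 90/112/120 occasions, M = 100/300/100,
buffers 13/16/20 km).

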