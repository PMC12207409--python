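# fountainscope

Hi-C analysis of loop-extrusion perturbations: expected / observed-over-
expected transforms, average extruded-loop-size estimation from contact-
probability derivatives, compartment scores and saddle-plot strength,
aggregate loop/domain pileups, fountain (extrusion-jet) detection with a
replicate-aware filter chain, and permutation enrichment tests — plus a 1D
loop-extrusion simulator and a synthetic-data generator so the entire
chain runs and is tested without any external data.

## Who this is for

Chromatin-organisation researchers analysing acute-depletion (degron) Hi-C
experiments on cohesin regulators — WAPL (the cohesin release factor), CTCF
(the extrusion barrier) and RAD21 (the cohesin kleisin) — and anyone who
needs a tested, self-contained implementation of the analysis steps those
studies rely on.

## The quantities at the core

- **Average extruded loop size**: the local maximum of the smoothed
  derivative d log₁₀ P / d log₁₀ s of the relative contact probability
  curve P(s). Stabilising cohesin (WAPL loss) moves this peak from ~100 kb
  to several hundred kb; removing CTCF as well lets it approach 1 Mb.
- **Compartment strength**: from a saddle plot (mean O/E per pair of
  compartment-score quantile groups), strength = (AA·BB)/AB² over the
  extreme 25% of quantiles. Loop extrusion antagonises compartmentalisation,
  so cohesin stabilisation lowers this number and cohesin removal raises it.
- **Fountains**: perpendicular O/E enrichment emanating from focal bases
  (preferential cohesin loading sites at enhancer-rich "open chromatin
  islands"). Candidates are score-profile peaks against an OCI-trained
  mask, filtered by Li-threshold prominence, bad-bin distance, mask
  correlation, ±60 kb replicate support, and noise/score quantile cuts.
- **Simulator**: extruders with two blocking legs on a lattice, oriented
  stochastic barriers, loading profiles with focal bases, and release/
  turnover kinetics; degron conditions are parameter presets
  (`untreated`, `wapl_off`, `ctcf_off`, `wapl_ctcf_off`, `rad21_off`).

## Worked example

```python
import fountainscope as fs

# simulate a WAPL-depletion condition and estimate the extruded loop size
params = fs.preset_params("wapl_off", seed=0)
result = fs.run_extrusion(params)
print(f"mean extruded loop size: {result.mean_loop_size_bp/1e3:.0f} kb")

full = fs.simulate_extrusion_map(params)          # adds distance-decay background
curve = fs.rcp_curve(full.matrix)
print(f"RCP derivative peak: {curve.estimated_loop_size/1e3:.0f} kb")
```

prints

```
mean extruded loop size: 421 kb
RCP derivative peak: 190 kb
```

— the same simulation under `"untreated"` gives 87 kb and 65 kb: the
capture-time loop span and the derivative-peak estimate both move up by
several-fold when cohesin release is switched off. The full
fountain pipeline on a synthetic genome with known truth:

```python
bench = fs.run_fountain_benchmark(fs.build_fountain_benchmark(seed=101))
print(bench.filter_log)
print(bench.precision_recall())
```

```
{'candidates': 392, 'li_threshold': 0.105, 'after_prominence': 20,
 'after_bad_bins': 20, 'after_correlation': 20, 'after_replicates': 20,
 'after_noise': 20, 'after_score': 20}
(1.0, 1.0)
```

392 candidate profile peaks reduce to exactly the 20 injected fountains
(precision 1.0, recall 1.0 at ±60 kb).

The numbered scripts under `analysis/` run the full study arc on simulated
and synthetic data — presets and loop sizes (01), RCP curves (02),
compartment strength and its restoration after extrusion removal (03),
primary/extended-loop and orientation-stratified pileups (04), fountain
calling and interaction-strength profiles (05), and permutation enrichment
(06) — writing tables under `results/`. A `fountainscope` command-line
interface exposes the same steps (`simulate`, `rcp`, `compartments`,
`pileup`, `fountains`, `enrich`).

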