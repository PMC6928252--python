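# nestedpls

Tri-linear (multiway) partial least squares regression with a
nesting-aware resampling quality-control layer for replicated in vivo
datasets.

Multiway PLSR models built from global averages hide the animal-to-animal
variability of in vivo measurements. `nestedpls` fits the standard
tri-linear two-block decomposition (condition × time × variable arrays,
iteratively extracted latent variables linked by an inner regression) and
then stress-tests every latent variable with resampling schemes that respect
the replicate hierarchy — all observations from one animal within a
condition × time cell move together:

* **jackknife (leave-one-out)** — drop one randomly chosen replicate per
  cell, re-average, refit;
* **subsample (leave-one-in)** — keep exactly one replicate per cell
  (an n-of-one dataset), refit;
* **paired mode** — couple the draw between the independent and dependent
  blocks through animal pairing identifiers;
* **randomization null** — shuffle each condition slab, refit, and flag
  weights beyond one null SD;
* **sign alignment** — collapse the sign indeterminacy of resampled latent
  variables before summarizing.

A weight whose resampled mean ± SD interval excludes zero is *robust*; one
whose interval covers zero is *fragile* and should not be mined for
interpretation, no matter how significant it looks against the
randomization null.

## Data format

Long (tidy) CSV, one row per observation:

```
condition,time,time_unit,variable,block,replicate_id,pairing_id,value
ATA,4,d,col_m,X,a1,animal1,0.92
```

`block` is `X` (independent) or `Y` (dependent); `replicate_id` groups all
observations one animal contributed within its condition × time cell;
`pairing_id` (optional) links the X and Y observations of one animal.
Different time grids per block are supported; missing dependent-only time
points are removed with `subset_design`, not padded with NaNs. Replicates
can also be simulated from summary tables (mean, SD, n) via
`simulate_replicates_from_summary`.

## Command line

```sh
# synthetic study-shaped data (bersi / lau / chit templates)
nestedpls simulate --study lau --seed 1 --replicate-noise 0.2 --out data/lau.csv

# global-average model + leave-one-condition-out CV (auto LV selection)
nestedpls fit --data data/lau.csv --config config.yaml --out runs/lau

# randomization null + one-SD significance table
nestedpls null --data data/lau.csv --config config.yaml --out runs/lau

# nested resampling ensembles
nestedpls resample --data data/lau.csv --config config.yaml --out runs/lau --method jackknife
nestedpls resample --data data/lau.csv --config config.yaml --out runs/lau --method subsample
```

Example `config.yaml`:

```yaml
standardization:
  preset: modes23        # or: bersi (day-0 subtraction + mode-3 scaling)
  zero_variance: strict
fit:
  n_lvs: auto            # argmin of the crossvalidated RMSE curve
  max_lvs: 5
  seed: 1
null:
  n_iter: 500
resample:
  n_iter: 500
```

Every stage stamps a manifest entry (command, config hash, seed, timestamp)
into the output directory so runs can be reproduced exactly.

## Python API

```python
import nestedpls as npl

ds = npl.read_long_csv("data/lau.csv")
raw = npl.average_replicates(ds)
spec = npl.modes23_spec()
settings = npl.FitSettings(n_lvs=3, seed=1)

cv = npl.loo_crossvalidate(raw, spec, settings, max_lvs=3)
n_lvs = npl.select_optimal_lvs(cv)

std, state = npl.standardize(raw, spec)
model = npl.fit(std.X, std.Y, npl.FitSettings(n_lvs=n_lvs, seed=1))

null = npl.build_null(raw, spec, model.settings, model, n_iter=500, seed=1)
mask = npl.classify_significant(model, null)

scheme = npl.ResamplingScheme(method="subsample", n_iter=500, seed=1, n_lvs=n_lvs)
ensemble = npl.run_ensemble(ds, scheme, spec, model.settings, reference_model=model)
table = npl.summarize_robustness(ensemble, raw, significance_mask=mask)
```

## Layout

| module | contents |
| --- | --- |
| `nestedpls.dataset` | long-table data model, validation, averaging, replicate simulation |
| `nestedpls.standardize` | baseline subtraction, mode-2/3 variance scaling, state for held-out folds and inversion |
| `nestedpls.npls` | tri-linear PLS core: unfolding, LV extraction, deflation, inner regression, prediction |
| `nestedpls.crossval` | leave-one-condition-out CV, RMSE-vs-LV curves, LV selection, prediction correlations |
| `nestedpls.nullmodel` | within-condition shuffling, null distributions, one-SD significance |
| `nestedpls.resampling` | jackknife/subsample/paired draws, ensembles, sign alignment, robustness tables |
| `nestedpls.synthetic` | planted tri-linear generators, study-shaped templates, noise regime sweeps |
| `nestedpls.cli` | `nestedpls` command line |
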