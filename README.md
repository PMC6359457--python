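# gaitsel

Multi-objective feature selection and gait-mode recognition toolkit.

`gaitsel` frames labeled multichannel biomechanical recordings (vertical hip
position, thigh angle, thigh moment), extracts time- and frequency-domain
features, and selects compact, accurate feature subsets by two routes:

- **Gradient-based sweep** (`gaitsel.gmofs`): an elastic-net-regularized
  constrained MLP whose per-feature input multipliers rank features; sweeping
  the regularization strength over a grid traces a (subset size, CV error)
  Pareto front with one classifier training per grid point.
- **Evolutionary search** (`gaitsel.mobbo`): binary biogeography-based
  optimization with four multi-objective selection schemes (vector-evaluated,
  non-dominated-sorting, niched-Pareto, strength-Pareto), maintaining an
  external non-dominated archive.

Supporting modules: windowing (`gaitsel.windowing`), feature extraction
(`gaitsel.features`), Pareto dominance/metrics (`gaitsel.pareto`),
cross-validation + majority-vote smoothing + the 300 ms real-time check
(`gaitsel.evaluation`), synthetic data (`gaitsel.synth`), and CSV/JSON glue
(`gaitsel.io`). No recorded subject data is required: the synthetic module
generates gait-like recordings and planted feature tables.

## Command line

```sh
gaitsel simulate --seed 1 --out rec.csv
gaitsel extract  --recording rec.csv --frame-ms 250 --increment-ms 50 \
                 --mode overlapped --out features.csv
gaitsel plant    --rows 240 --cols 30 --informative 5 --out table.csv
gaitsel gmofs    --table table.csv --alpha 0 --lambda-grid "0:1:30,40:10:150" \
                 --hidden 5 --threshold 0.95 --seed 1 --out gmofs.json
gaitsel mobbo    --table table.csv --variant nsbbo --pop 100 --gens 1000 \
                 --mu 0.04 --elites 2 --folds 10 --seed 1 --out archive.json
gaitsel compare  --archive gmofs g.json --archive nsbbo a.json --out-prefix cmp
gaitsel evaluate --table features.csv --classifier svm-rbf --sigma 1 \
                 --mvf-q 5 --out report.json
gaitsel run      --config config.yaml --out-dir artifacts/
```

`run` executes the full synthetic pipeline (simulate → extract → select →
compare → evaluate) from one YAML config; identical seeds yield
byte-identical JSON artifacts.

## Notes

- The front-quality score `normalized_hypervolume` is the mean over front
  points of the product of objective values (smaller is better). The
  classical indicator is available separately as `dominated_hypervolume`.
- Variance, skewness, and kurtosis use the population convention (divide by
  frame length). Counter thresholds (ZC/SSC/WAMP) default to 0.01 x the
  per-channel standard deviation and are configurable.
- Normalization statistics are fitted on training rows only by default; a
  `normalize_scope="global"` switch standardizes whole tables instead.
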