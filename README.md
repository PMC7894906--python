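# adaptref

Static and adaptive (individualised) reference ranges for longitudinally
monitored biomarkers, with a simulation study comparing their ability to
detect abnormal observations.

Three methods share one long-format input (`subject,index,value` CSV):

- **static** — population-based two-sided normal tolerance intervals
  (Howe tolerance factor), identical for every observation of a subject,
  built leave-one-subject-out from the rest of the cohort; includes the
  Harris–Boyd between-group variance-ratio check for stratification.
- **bayes** — a fully Bayesian hierarchical normal model with
  subject-specific within-subject variances (normal subject means,
  inverse-gamma variance priors), fitted by a conjugate Gibbs sampler on
  per-subject sufficient statistics; reference limits are empirical
  quantiles of the posterior predictive of the next observation.
- **em** — the same hierarchy point-estimated by maximum likelihood via
  EM on three complete-data sufficient statistics, plus a streaming
  (per-observation) approximation that never stores raw data; limits come
  from a plug-in normal predictive.

Classical individual and universal-variance Z-score baselines are also
provided (`adaptref.zscore`).

For both adaptive methods the first two observations of a subject fall
back to the static tolerance interval (a within-subject variance needs at
least two points).

## CLI

One entry point with subcommands (exit codes: 0 ok, 1 usage, 2 data
error, 3 numerical failure; `--config file.yaml` pre-populates options,
explicit flags win; `--log` fits on the natural-log scale and returns
limits on the raw scale):

```sh
adaptref static   --input data.csv --subject A --p 0.95 --confidence 0.95 --out band.csv
adaptref zscore   --input data.csv --subject A --method individual --out scores.csv
adaptref bayes    --input data.csv --subject A --alpha 0.05 --iters 4000 --burnin 1000 \
                  --seed 7 --out band.csv --draws draws.csv
adaptref em       --input data.csv --subject A --alpha 0.05 --out band.csv
adaptref stream   --input stream.csv --state state.json --out alerts.csv
adaptref simulate --grid grid.yaml --methods static,bayes,em --replicates 200 --seed 11 \
                  --out results.csv
```

`stream` keeps a JSON state (per-subject counts, means, mean squares and
the sufficient statistics only) and applies one streaming-EM update per
row; re-running with the same state file resumes where it left off.

Band CSVs have columns `subject,index,value,lower,upper,atypical,method`.

## Simulation study

`adaptref.simulation` simulates hierarchical-normal populations
(subject means `N(mu, tau2)`, observations `N(mu_i, sigma_i^2)` with
inverse-gamma-distributed heterogeneous variances controlled by the
ratios `r1 = Var(WSV)/BSV`, `r2 = E(WSV)/BSV`), holds out each subject's
final observation, randomly assigns case/control status (cases' finals
are shifted `3 sigma_i` away from the subject's true mean), scores the
finals with each method's two-sided tail probability, and reports AUC,
sensitivity and specificity per scenario.

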