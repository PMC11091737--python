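# methclock

DNA-methylation age clocks for mammalian species: build sparse
penalized-regression clocks on transformed age, apply existing clock
coefficient tables (with inverse age transformations), evaluate them by
leave-one-out (LOO) and leave-one-species-out (LOSO) cross-validation,
pre-filter CpG probes, detect technical outlier arrays, and run
(meta-)EWAS of age. A seeded synthetic-cohort generator provides all
inputs, so nothing needs to be downloaded.

## Concepts

An epigenetic clock is a sparse linear model on CpG methylation fractions
("beta values", in [0, 1]):

    F(age) = intercept + Σ_p coef_p · beta_p

where `F` is an invertible, strictly increasing age transformation that may
depend on species life-history parameters (maximum lifespan `L`, gestation
`g`, age of sexual maturity `m`, AnAge-style). Registered transforms:
`identity`, `log_linear`, `relative_age`, `loglog_relative_age`,
`relative_adult_age`. Predicted DNAm age is `F⁻¹(linear predictor)`.

Clocks are fit by elastic net (mixing `alpha`, 1 = LASSO) with the penalty
`lambda` chosen by internal k-fold CV over a 100-point log-spaced path.
LOO/LOSO use a single `lambda` selected once on the full data and reused in
every fold (per-fold re-tuning available via `--per-fold-lambda`).

## CLI

One binary, `methclock`, with subcommands (global flags: `--quiet`,
`--verbose`, `--config config.yaml`):

```
# generate a seeded 3-species synthetic cohort (betas, sheet, species, truth)
methclock simulate --seed 42 --out sim/

# probe pre-filtering: mappability list, middle window, detection p-values
methclock filter --betas sim/betas.csv --middle 0.3 0.7 \
    [--mappable probes.txt] [--detection-p pvals.csv --p 0.05 --max-fail 0] \
    --out filtered/

# QC: inter-array correlation, average-linkage clustering, outlier flags
methclock qc --betas sim/betas.csv --corr-threshold 0.9 --out qc/

# build a clock
methclock build --betas sim/betas.csv --sheet sim/sheet.csv \
    --species sim/species.csv --transform loglog_relative_age \
    --alpha 0.5 --folds 10 --seed 42 --out clock/

# apply a clock (any conforming coefficient CSV)
methclock predict --betas sim/betas.csv --clock clock/clock.csv \
    --sheet sim/sheet.csv --species sim/species.csv --out pred/

# cross-validate (loo or loso)
methclock cv --mode loso --betas sim/betas.csv --sheet sim/sheet.csv \
    --species sim/species.csv --transform relative_age --seed 42 \
    --save-fold-clocks --out cv/

# per-CpG association with age, optionally stratified + Stouffer meta
methclock ewas --betas sim/betas.csv --sheet sim/sheet.csv \
    --outcome age --by species --out ewas/

# list bundled + user-installed clocks
methclock registry [--user-dir my_clocks/]
```

Clock files are CSVs with columns `var,coef`, one `(Intercept)` row, and
`#`-prefixed metadata header lines carrying the clock name, transform and
its parameters; the reader also accepts common column aliases
(`CpG`/`probe`, `beta`/`Coef`). Drop conforming CSVs in a directory and
point `registry --user-dir` (or `ClockRegistry`) at it.

## Package layout

- `methclock.core` — domain types (BetaMatrix, SampleSheet,
  SpeciesCharacteristics, TransformSpec, ClockDefinition), transform
  registry, clock application
- `methclock.build` — elastic-net fitting and lambda selection
- `methclock.crossval` — LOO / LOSO evaluation
- `methclock.filtering` — mappability / middle / detection-p probe filters
- `methclock.qc` — inter-array correlation, hierarchical clustering,
  outlier flagging
- `methclock.ewas` — per-CpG association and Stouffer meta-analysis
- `methclock.io` — readers/writers for all table dialects, clock registry
- `methclock.simulate` — seeded synthetic cohort generator
- `methclock.cli` — the `methclock` entry point
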