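# labelkin

Estimation of lymphocyte production and loss rates from in vivo
heavy-water (²H₂O) labeling studies, with a synthetic-cohort generator
for end-to-end testing.

The pipeline quantifies, per individual:

1. **Body-water kinetics** — the urine ²H enrichment curve U(t)
   (exponential approach to plateau during labeling, exponential
   washout after), fit jointly with the granulocyte saturation curve to
   obtain the amplification factor *c* and the scaling maximum *M*.
2. **Subset kinetics** — scaled DNA enrichment of sorted lymphocyte
   subsets modeled as a 1- or 2-component kinetic mixture (fractions
   αᵢ, production rates pᵢ), fit jointly with trend-normalized cell
   counts X₀·e^((p−d)t) by maximum likelihood (arcsin-√ transformed
   enrichment, log10 counts, per-stream variance profiled out). The
   number of components is chosen by an extra-sum-of-squares F-test;
   95% CIs come from a residual bootstrap on the transformed scales.
3. **Cell dynamics** — OLS leukocyte trend, normalized subset counts
   (trend × fraction), and loss rates d = p − r from the fitted net
   growth rate.
4. **Excision circles** — B-cell replication history and coding-joint
   frequencies from KREC qPCR Ct values (referenced to the U698-DB01
   control line), and TREC content per cell.
5. **Cohort report** — group medians, fold changes, total daily
   production, Mann–Whitney (exact for small groups) and
   Kruskal–Wallis + Dunn comparisons.

## CLI

All randomness flows from a single `--seed`; reruns are byte-identical.

```bash
# generate a synthetic cohort (study-design preset: 6 patients vs 10
# steady-state controls, configured production/loss-rate folds)
labelkin simulate --seed 11 --out runs/data

# fit every individual (body water -> scaling -> subsets); optional CIs
labelkin fit --data runs/data --out runs/fits --n-boot 200 --seed 11

# cohort folds, tests, KREC divisions
labelkin report --fits runs/fits --data runs/data --out runs/report

# or everything at once
labelkin all --seed 11 --out runs
```

`simulate` accepts a YAML config (`--config`) with keys `n_patients`,
`n_controls`, `jitter`, `sd_enrichment`, `sd_counts`, and per-subset
`production_folds` / `loss_folds` overrides.

Input tables are plain CSV; dialects are documented in
`labelkin.io` (enrichment, counts, qPCR, groups).

## Layout

```
src/labelkin/
  labelmodel.py        closed-form U(t), label-fraction curves, scaling,
                       isotope standard-curve calibration
  fitting.py           ML fits, model selection, residual bootstrap
  celldynamics.py      leukocyte trend, count normalization, loss rates
  excision_circles.py  TREC/KREC formulas
  cohort_report.py     fold changes and nonparametric group tests
  synthdata.py         ground-truth synthetic study generator
  io.py, cli.py        CSV validation, manifests, command line
```
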