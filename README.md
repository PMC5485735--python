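# nmrprofiler

Metabolic profiling of plasma by ¹H-NMR for small two-group case–control
designs — the workflow used to discriminate pediatric type 1 diabetes
mellitus (T1DM) patients from matched non-diabetic controls, reimplemented
as a tested, reusable Python package.

A 1D plasma ¹H-NMR spectrum is reduced to a fixed *metabolic phenotype* by
integrating the signal over 110 predefined chemical-shift regions, one
variable per region (each proxies the relative concentration of the
metabolite(s) resonating there; 15 regions are glucose-dominated and can be
excluded to give a 95-variable, glucose-free profile). The statistical
pipeline is then:

1. **Preprocessing** — mean-centering and Pareto scaling
   (x′ᵢⱼ = (xᵢⱼ − μⱼ)/√sⱼ), the standard damping of intense NMR signals.
2. **PCA quality control** — NIPALS PCA score plots for clustering and
   confounder staining, with Hotelling's T² (limit
   A(N²−1)/(N(N−A))·F₁₋α(A, N−A)) and DModX (limit
   √F₁₋α(K−A, (N−A−1)(K−A))) outlier screening.
3. **OPLS-DA** — orthogonal projections to latent structures discriminant
   analysis with one predictive and (by default) one orthogonal component;
   fit quality R²X(cum)/R²Y(cum), predictive ability Q²(cum) = 1 − PRESS/SS
   by stratified sevenfold cross-validation; per-variable S-line statistics
   p(ctr)[1] (covariance with the predictive score) and p(corr)[1]
   (correlation-scaled loading), and VIP with a jack-knife cvSE over the CV
   submodels.
4. **Univariate testing** — pooled-variance two-sample t tests with
   Benjamini–Hochberg correction and signed %-change of the case mean
   relative to the control mean.
5. **Selection** — a variable is a *discriminator* iff all three criteria
   hold: BH-adjusted p < 0.05, |p(corr)[1]| > 0.6, VIP > 0.5.

Because the original clinical spectra are not publicly deposited, the
package ships a seedable synthetic-data generator whose default template
carries the published group summary statistics (mean ± SD per group for the
17 published regions: glucose up ~23–68% in T1DM, lipids down ~17–36%,
serine/tryptophan/cysteine down ~25–64%; null effects elsewhere) with
log-normal marginals, moment-matched so the template reads exactly like the
published table, and optional within-metabolite correlation blocks. Full
synthetic spectra (one Lorentzian per region) can be rendered so the binning
stage is exercised end to end.

## Worked example

Generate a 7 + 7 synthetic cohort and run the full analysis:

```sh
profiler synth profiles --n-case 7 --n-control 7 --seed 1 \
    --out matrix.csv --meta meta.csv
printf 'matrix: matrix.csv\nmetadata: meta.csv\nout_dir: results\n' > run.yaml
profiler run --config run.yaml
```

which prints

```
110var: R2X(cum)=0.554 R2Y(cum)=0.969 Q2(cum)=0.869 selected=13
95var:  R2X(cum)=0.386 R2Y(cum)=0.978 Q2(cum)=0.658 selected=7
```

Reading: on the full 110-variable profile the OPLS-DA model explains 55% of
the X-variation and 97% of the class separation, and its sevenfold
cross-validated predictive ability Q²(cum) = 0.87 is strongly positive, so
the group discrimination is not an artifact of overfitting. Thirteen
variables pass all three selection criteria — the glucose regions with
negative p(corr)[1] (higher in T1DM; controls are coded +1, cases −1) and
the lipid/amino-acid regions with positive p(corr)[1] (lower in T1DM).
Refitting after removing the 15 glucose regions (95 variables) still yields
Q²(cum) = 0.66 with the lipid and amino-acid discriminators intact, i.e.
the separation does not rest on glucose alone. `results/` contains the
per-variable tables (`results_110.csv`, `results_95.csv`), score tables,
outlier report, S-line table, `model_summary.json` (config echo, seeds,
conventions) and figures rendered from those tables.

The same analysis is available as a library (`nmrprofiler.run_pipeline`,
or the individual functions `fit_scaling`, `fit_pca`, `fit_oplsda`,
`cross_validate`, `sline`, `vip_with_cvse`, `univariate_table`,
`select_discriminators`).

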