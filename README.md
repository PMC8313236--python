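# monoculture

Phylogenetic multilevel meta-analysis of how within-group relatedness
affects mortality and pathogen abundance across species.

## The problem

Living in groups of relatives brings kin-selected benefits, but
genetically uniform groups can be more susceptible to pathogens — the
"monoculture effect" known from clonal crops. Whether higher
within-group relatedness ultimately raises or lowers mortality in
natural populations is a comparative question: evidence is scattered
across dozens of studies on bacteria, plants and animals, each
reporting different statistics at different scales. This package
provides the full meta-analytic machinery to synthesise such evidence:

* **Effect sizes** (`monoculture.effect_sizes`): reported statistics
  (t, F, χ², r) and group summaries are converted to Pearson
  correlations, Fisher-transformed to `Zr = atanh(r)` with sampling
  variance `1/(n − 3)` (n = number of groups); differences in
  across-group *variability* are captured by the log
  coefficient-of-variation ratio `LnCVR = ln(CV_H/CV_L)` with its
  delta-method sampling variance. A Monte-Carlo estimator recovers `r`
  from per-group descriptive statistics.
* **Phylogeny** (`monoculture.phylo`): a tree is built from ranked
  taxonomy, Grafen branch lengths make it ultrametric (node height
  `((k−1)/(S−1))^p`), and the species correlation matrix — the shared
  fraction of root-to-tip history — enters the model as the
  phylogenetic covariance structure.
* **The model** (`monoculture.bpmm`): a Bayesian phylogenetic
  multilevel meta-regression (BPMM),

      y_i = x_i'β + u_study + u_species + u_phylo + m_i + e_i,

  with `u_phylo ~ N(0, σ²_phylo A)` and a fixed-variance measurement
  term `m_i ~ N(0, v_i)` implementing inverse-variance weighting.
  Fitting is conjugate Gibbs sampling (numba-compiled, with a numpy
  reference engine), wrapped in a scikit-learn-style estimator
  `PhyloMetaRegression` with `fit`, `get_params` and trailing-underscore
  fitted attributes. Summaries are KDE posterior modes, 95%
  highest-posterior-density intervals, pMCMC, Gelman–Rubin PSRF and
  variance fractions.
* **The battery** (`monoculture.analysis`): intercept-only and
  moderator models (pathogen presence × manipulation, relatedness
  manipulation, kin structure; LnCVR variants), all pairwise level
  contrasts computed per draw, verification refits, Egger-style
  publication-bias regression, funnel-table export, and an abstract
  relevance scorer for literature screening.
* **Synthetic data** (`monoculture.simulate`): datasets with the real
  evidence base's shape (56 species, 75 studies, 210 effect sizes,
  LnCVR companions) and known ground truth, plus raw group-level study
  simulation and a publication-selection operator.

## Worked example

```python
from monoculture import SyntheticTruth, simulate_effect_table, run_analysis

truth = SyntheticTruth()          # exp. absent-vs-present contrast = -0.4
records, corr, info = simulate_effect_table(truth, seed=42)

res = run_analysis(records, corr, "m3_pathogen_by_studytype",
                   profile="desk", seed=7)
c = res.contrasts
row = c[(c.level_a == "absent|experimental")
        & (c.level_b == "present|experimental")].iloc[0]
print(f"contrast PM = {row.pm:.3f}, "
      f"CI = ({row.ci_low:.3f}, {row.ci_high:.3f}), pMCMC = {row.pmcmc:.4f}")
```

prints

```
contrast PM = -0.336, CI = (-0.480, -0.150), pMCMC = 0.0007
```

— the posterior mode of the mortality contrast between pathogen-absent
and pathogen-present conditions in experimental studies. The true
generating contrast is −0.4; the 95% credible interval excludes zero,
so under experimental pathogen manipulation relatedness has credibly
opposite effects depending on pathogen presence in this synthetic
dataset. `res.model.variance_fraction("phylo")` gives the percentage
of heterogeneity attributable to phylogeny, and
`res.model.psrf_` the convergence diagnostics.

The same pipeline runs from the shell:

```bash
monoculture simulate --seed 42 --out sim/
monoculture fit sim/effect_sizes.csv sim/phylo_correlation.csv \
    --analysis-id m3_pathogen_by_studytype --profile desk --seed 7 --out fit/
monoculture bias sim/effect_sizes.csv sim/phylo_correlation.csv \
    --profile desk --seed 7 --out bias/
```

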