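# diallel

Combining-ability analysis for balanced half-diallel trials (Griffing
Method 2 / Model 1) grown as randomized complete blocks in one or more
environments, plus a matching trial simulator with known ground truth.

Given plot-level phenotype records for `p` parents and their `p(p-1)/2` F1
hybrids, the package computes:

- **Combining-ability effects** — grand mean, GCA effects `g_i`, SCA effects
  `s_ij` with standard errors, t-test star codes, and LSDs for the three
  standard effect contrasts (`g_i - g_j`, half-sib `s_ij - s_ik`, disjoint
  `s_ij - s_kl`).
- **ANOVA** — per-environment RCBD tables and a combined multi-environment
  table with the genotype and genotype-by-environment sums of squares each
  partitioned into GCA and SCA parts (all identities exact on balanced data;
  fixed-effects F tests against the pooled residual).
- **Genetic parameters** — variance components
  `sigma2_GCA = (MS_GCA - MS_SCA) / (r (p+2))`,
  `sigma2_SCA = (MS_SCA - MS_error) / r`, additive/dominance variances,
  Baker's ratio `2 sigma2_GCA / (2 sigma2_GCA + sigma2_SCA)`, and broad-
  and narrow-sense heritabilities on the entry-mean error basis.
- **Heterosis** — mid-parent and best-parent percentages with their LSD
  significance tests, trait-direction-aware favorability calls, and Fisher
  LSD mean comparisons with compact letter display.
- **Simulation** — balanced multi-environment trials under the
  additive-dominance model with per-component seed substreams, plus built-in
  variance presets at published magnitudes for an 11-parent melon trial.

## Input format

Delimited text (comma or tab, auto-detected), one row per plot per trait:

```
environment,replicate,parent_a,parent_b,trait,value
non-saline,rep1,P1,P1,FY,38.2
non-saline,rep1,P1,P2,FY,44.6
```

Parent labels are `P1..Pp` or bare integers; `parent_a == parent_b` is a
parent entry, and crosses are canonicalized so `(j, i)` equals `(i, j)`. The
design must be fully balanced — unbalanced or missing plots are rejected,
never imputed.

## CLI

```sh
# simulate a trial from a built-in preset (11 parents, 2 reps) or a YAML config
diallel simulate --preset FY non-saline --out sim/ --seed 1
diallel simulate --config sim.yaml --out sim/ --seed 1

# run the full analysis
diallel analyze --input sim/phenotypes.csv --config run.yaml --out report/
```

`run.yaml` declares the traits with their favorable direction, plus optional
alpha and rounding:

```yaml
traits:
  FY: true     # higher is better
  SCL: false   # lower is better
alpha: 0.05
rounding: 2
```

The report bundle contains one combined-ANOVA table per trait, and per
environment: genetic parameters, GCA and SCA effect tables with LSD footers,
heterosis tables, and mean comparisons — all rendered from `summary.json`,
the machine-readable record of every statistic at full precision.

## Library use

```python
import diallel as dl

plots, truth = dl.simulate(dl.paper_preset("FY", "non-saline", seed=1))
table = dl.entry_means(plots, "non-saline", "FY")
effects = dl.estimate_effects(table)          # mu, g_i, s_ij (saturated fit)
params = dl.estimate_genetic_params(plots, "non-saline", "FY")
print(params.ratio, params.h2_broad, params.h2_narrow)
```

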