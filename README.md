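# pcbscan

Sex-stratified transcriptome-wide linear mixed model scans for serum
polychlorinated-biphenyl (PCB) exposure and PCB × white-blood-cell
interaction effects, with a fully synthetic cohort generator so every stage
of the analysis is testable at desk scale.

## The problem

Prospective blood-based cohort studies ask whether exposure to persistent
pollutants such as PCBs (congeners 118, 138, 153, 156, 170, 180) shifts
whole-blood gene expression, whether the response differs between females
and males, and whether it is modulated by the composition of white blood
cells (NK, B, monocytes, granulocytes, CD8T, CD4T) — the cell mixture both
confounds expression and may sit on the causal path. Such data come with
strong technical batch structure (microarray scan dates) and strongly
co-accumulating exposures, so the workhorse is a per-transcript linear mixed
model. For transcript expression $Y_i$ of subject $i$:

$$Y_i = \alpha + \beta_1\,\mathrm{PCB}_i + \beta_2\,\mathrm{WBC}_i
      + \beta_3\,(\mathrm{PCB}_i \times \mathrm{WBC}_i)
      + \beta_4\,\mathrm{FE}_i + u_{a(i)} + \varepsilon_i$$

with fixed confounders $\mathrm{FE}$ (cohort, sex, future cancer type, age,
BMI, smoking), a Gaussian scan-date random intercept
$u_a \sim N(0, \sigma_u^2)$ and residual $\varepsilon_i \sim N(0,
\sigma_e^2)$. Each transcript is tested by a maximum-likelihood ratio test
of the model with vs without the variable of interest (one congener, or one
congener × cell-type product), followed by Benjamini–Hochberg FDR control
within the scan. Around the scan sit the supporting stages: pixel-coverage
probe filtering, k-nearest-neighbour imputation (k = 15, Euclidean),
quantile normalization, reference-based estimation of WBC fractions from
methylation (constrained projection onto purified-cell signatures),
variance-inflation-factor screening (threshold 4) that forces one congener
per model and drops granulocytes, noncentral-F power planning, and
stratified downstream summaries (sex × future-case count tables, sex
comparisons of exposure, gene-list overlap, hypergeometric
over-representation, fold-change signatures, time-to-diagnosis
correlations).

Because the human cohort data are access-restricted, the package ships a
first-class generator that emulates the study's statistical structure —
512 subjects (217 future lymphoma cases / 295 controls), six correlated
log-normal exposures with a female shift on congeners 118/156/170/180,
Dirichlet cell fractions, batch random intercepts, and sparse planted
effects with known ground truth — so calibration, FDR control and power can
be measured rather than assumed.

## Worked example

```python
import pcbscan as pk

cohort = pk.generate_cohort(n=512, n_cases=217, seed=1)

# which congeners differ between the sexes?
print(pk.exposure_sex_ttest(cohort).round(4))

# plant a PCB156 x B-cell interaction in 5% of 1000 transcripts at the
# effect size giving 80% power at the expected BH cutoff, then scan
truth = pk.SimulationTruth.null(1000, sigma2_u=0.2, sigma2_e=1.0)
beta = pk.interaction_effect_for_power(cohort, 156, "B", power=0.8, alpha=0.0025)
planted = truth.plant_interactions(156, "B", beta, fraction=0.05, seed=1)
expr = pk.generate_expression(cohort, truth, seed=2)

res = pk.interaction_scan(expr, cohort, pcb=156, wbc="B")
hits = res.significant
true = set(expr.index[planted])
print("significant at FDR 0.05:", len(hits))
print("true positives:", len(hits & true), "false positives:", len(hits - true))
```

Output:

```
          t       p
pcb
118  2.9666  0.0032
138  1.5359  0.1252
153 -0.0103  0.9918
156  3.5219  0.0005
170  3.4690  0.0006
180  3.1589  0.0017
significant at FDR 0.05: 39
true positives: 36 false positives: 3
```

The four female-shifted congeners (118, 156, 170, 180) are the ones with
p < 0.05 in the sex comparison, and the interaction scan recovers 36 of the
50 planted transcripts with 3 false discoveries (empirical FDR 0.077 on this
single draw; the BH target of 0.05 holds in expectation across seeds).

A command-line interface mirrors the library:

```bash
pcbscan synth --n 512 --cases 217 --seed 1 --out run/
pcbscan scan --expr run/expression.tsv --cohort run/cohort.tsv \
    --voi PCB156 --interaction B --stratum sex=F --out run/scanF.tsv
pcbscan pipeline --config config.yaml
```

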