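# protlmm

Protein-level significance analysis, quantification and study design for
**label-free LC-MS/MS proteomics with complex experimental designs**
(factorials, time courses), built on per-protein linear mixed-effects
models.

Label-free shotgun proteomics quantifies each protein through a variable
set of LC-MS *features* (peptide ions at given charge states) across many
instrument runs. Features differ in ionization efficiency, carry
interferences, and drop out of individual runs — so simply averaging
feature log-intensities per sample loses accuracy and sensitivity.
`protlmm` instead fits one linear model per protein that pools **all**
features and **all** conditions of the experiment, and derives every
downstream quantity from that fit. It is aimed at proteomics analysts who
need protein-level statistics out of a long-format feature-intensity
table without writing model code.

## The model

For feature *i* = 1…*I*, condition *j* = 1…*J*, biological replicate
*k* = 1…*K* and technical replicate *l* = 1…*L*, the observed
log-intensity is decomposed as

```
y_ijkl = μ + F_i + C_j + (F×C)_ij + S(C)_k(j) + ε_ijkl ,   ε ~ N(0, σ²_Error)
```

with treatment coding (μ is the expected log-intensity of the first
feature / first condition / first replicate). `F` captures between-feature
intensity differences, `C` the condition effects of interest, `F×C`
feature interferences, and `S(C)` the biological replicate nested within
condition (replaced by a global subject term for repeated-measures /
time-course designs, which is detected automatically from subject
identifiers). The subject term has two interpretations:

* **reduced scope** — subjects are fixed effects; conclusions are
  restricted to the observed replicates (screening experiments); fit by
  (iteratively re-weighted) least squares;
* **expanded scope** — subjects are random, `S ~ N(0, σ²_S)`; conclusions
  generalize to the population (validation experiments); fit by REML.

From the fit, a biological comparison is a zero-sum contrast over
condition means, tested with `t = c'θ̂ / sqrt(c'Cov(θ̂)c)` against a
Student distribution (residual df in the reduced scope; Satterthwaite df
in the expanded scope), with Benjamini–Hochberg FDR control across
proteins. The same linear combinations yield model-based protein
quantification per condition or per biological replicate with t-based
confidence intervals. Heteroscedastic technical variance is handled by
iterative least squares with loess-smoothed |residual|-vs-fitted weights.
Features missing in an entire condition can be imputed at the average
per-run minimum log-intensity, handled by dropping the `F×C` interaction,
or removed. For balanced future designs the minimal detectable log fold
change follows

```
δ² ≥ σ²_Error / (IKL) · (t_{1-β, df} + t_{1-α/2, df})² ,
α = (1-β) q / (1 + (1-q) m0/m1),   df = IJK(L-1) + (I-1)J(K-1).
```

## Worked example

Simulate a 2×2×2 factorial study (8 conditions × 2 cultures × 3 runs =
48 runs, 50 proteins of which 10 are differential) and compare the two
cell lines after six hours of normoxia:

```python
import protlmm as pl

table, truth = pl.generate_factorial(n_proteins=50, sigma_subject=0.0, seed=7)
comp = pl.ComparisonSpec("low-vs-high@normoxia-6h",
                         {"low:normoxia:6": 1.0, "high:normoxia:6": -1.0})
bundle = pl.analyze(table, comparisons=[comp], quant_targets="condition")
print(bundle["results"].sort_values("adj.pvalue").head())
```

```
Protein                   Label    log2FC       SE     Tvalue    DF        pvalue    adj.pvalue status
    P36 low-vs-high@normoxia-6h -2.019819 0.050423 -40.057703 472.0 5.950269e-154 2.975135e-152     ok
    P27 low-vs-high@normoxia-6h -0.981180 0.042854 -22.896039 632.0  5.985989e-85  1.496497e-83     ok
    P16 low-vs-high@normoxia-6h -1.969987 0.066456 -29.643427 232.0  7.499127e-81  1.249855e-79     ok
    P40 low-vs-high@normoxia-6h -1.064968 0.048257 -22.068538 472.0  1.121866e-74  1.402333e-73     ok
    P30 low-vs-high@normoxia-6h -1.015369 0.054429 -18.654991 392.0  4.800237e-56  4.800237e-55     ok
```

`log2FC` is the contrast of model-based condition means on the log2
scale (here the simulated effects were planted in the high-invasive
line, hence the negative signs); `DF` is the residual df of each
protein's fit (it varies with the protein's feature count). At FDR 0.05
the analysis declares 12 of 50 proteins significant and recovers all 10
truly differential ones. The same bundle carries condition-level
quantifications with 95% CIs:

```
Protein          Target TargetType  Estimate       SE     CIlow    CIhigh  Level  NMissing status
    P01  low:normoxia:6  condition 18.339399 0.030711 18.279075 18.399723   0.95         0     ok
```

and data-driven power inputs — feeding the median residual variance
(0.089) back into the sample-size formula gives a minimal detectable
log2 fold change of 0.126 (fold change 1.09) for a future J=8, K=2, L=3
design.

The same workflow is available from the shell:

```bash
protlmm simulate factorial --n-proteins 50 --seed 7 --out table.csv
protlmm run --input table.csv --comparisons comparisons.yaml --out results/
protlmm power --q 0.05 --beta 0.2 --m0m1 9 --i 2 --j 8 --k 2 --l 3
```

See `docs/methods.md` for the full statistical details, defaults and
limitations.

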