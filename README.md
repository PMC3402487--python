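# netprog

Network-propagated gene signatures and survival-SVM prognostic models.

## The problem

Published prognostic gene-expression signatures for the same cancer
phenotype barely overlap: supervised gene selection is dominated by the
patient subset used to derive each list, and membership in such a list
says little about a gene's mechanistic role. `netprog` implements the
alternative: pool the evidence — membership of genes in published
signatures and per-gene somatic-variant counts — as weighted seeds of a
random walk with restart on a protein-protein interaction network, and
keep the genes whose steady-state visiting probability is significant
against permuted-seed nulls. The resulting *network signature* is chosen
for inferred mechanistic importance, independently of any training
cohort, and is then evaluated for clinical value with a kernel survival
SVM. It is aimed at computational biologists studying
network-based data integration and prognostic modelling of censored
outcomes.

## The model

**Propagation.** With `W` the column-normalized adjacency matrix of the
interaction network and `p0` the seed distribution,

    p(t+1) = (1 − r) · W · p(t) + r · p0,      r = 0.5,

iterated until the L1 change drops below 1e-6 (the fixed point solves
`(I − (1 − r)W) p = r·p0`, used as an exact oracle and for fast
permutation nulls). Seeds combine two channels with equal total weight:
`p0_i = ½·s_i/Σs + ½·m_i/Σm`, where `s_i` counts the signatures
containing gene i and `m_i` its catalogued somatic variants ("NEM"
integration; "NE"/"NM" use one channel). Significance: 1000 runs with
the seed vector shuffled across nodes give each gene a *local* p (vs its
own null scores — absorbs hub effects) and a *global* p (vs the pooled
null); genes with both below 0.05 form the signature.

**Prognosis.** A ranking survival SVM with Gaussian kernel
`K(x,y) = exp(−‖x−y‖²/2σ²)` scores patients so that, for every
comparable pair (t_i < t_j, event i observed), the shorter-lived member
is pushed a margin higher — higher score means higher risk. `c` and `σ`
are selected from {10⁻⁵…10⁵} × {10⁻⁵…10⁵} by 5×5-fold cross-validated
Harrell C-index; the model trains on one cohort and is tested on an
independent one. Patients split at the median score into low/high-risk
groups compared by Kaplan-Meier curves, the log-rank test, and Cox
proportional-hazards models; a stratified analysis asks whether adjuvant
chemotherapy benefit is confined to predicted high-risk patients.

A synthetic-data module generates all inputs with the structure the
analysis assumes — a scale-free network with a planted dense driver
module, evidence channels enriched in it, and cohorts whose module genes
load on a latent risk driving exponential relapse hazards with a
treatment-by-risk interaction — so the whole pipeline runs with no
downloads. See `docs/methods.md` for assumptions and limitations.

## Worked example

```sh
netprog simulate --seed 1 --out data/
netprog run-all --config data/ --seed 1 --n-perm 1000 --out runs/nem
```

which prints

```
signature size 92; test C-index 0.679; log-rank p 0.001275
```

On this benchmark the walk keeps 92 of 2000 genes (80 seed genes, 12
added purely by network context). A survival SVM trained on those genes
in cohort 1 ranks cohort 2's relapse times with concordance 0.68 —
between the random-gene baseline (median ≈ 0.56 over 10 random sets of
matched size) and the ceiling of a model trained directly on the 80
planted informative genes (≈ 0.73) — and the median-split risk groups
separate at log-rank p ≈ 0.001 (hazard ratio ≈ 3.1).
`runs/nem/` holds the full JSON report, per-sample scores/groups, and
the signature gene list. The same library calls are available in
Python via `netprog.pipeline.RunConfig` / `run_full_pipeline`, and
`netprog compare`, `baseline`, `ctx`, `prioritize`, `train`, `evaluate`
expose the individual stages.

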