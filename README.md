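# cytostrat

Blood mass-cytometry immunophenotyping and patient stratification for lupus
nephritis (LN) cohorts — a tested, reusable re-implementation of the
analysis chain that stratifies LN patients into three immunologic groups
from circulating immune-cell profiles and links them to renal pathology and
treatment response.

LN treatment decisions lean on kidney-biopsy histology, which predicts
outcome poorly.  Blood immunophenotyping by CyTOF offers a noninvasive
window: after arcsinh transformation, QC, batch correction and two-level
graph clustering of per-sample event tables, samples are summarized as
within-lineage subset proportions plus a cytometric type-I-interferon
score,

```
IFN-I score = Σ_m (x_m − μ_m) / σ_m ,   m ∈ {MX1, ISG-15, Siglec-1}
```

where `x_m` is the sample median of marker `m` (MX1/ISG-15 over all cells
of their panels, Siglec-1 over myeloid cells) and `μ_m, σ_m` are control
means and SDs; a sample is IFN-elevated above the control mean + 3 SD of
control scores.  K-means (K = 3) on z-scored features defines the groups,
anchored semantically: **G0** (cluster holding the controls; quiescent),
**G1** (higher mean IFN score; interferon-high), **G2** (the remainder;
enriched for granzyme-B⁺ T cells, CD21-low naive B cells and low-density
neutrophils).  Covarying-neighborhood analysis tests phenotypes against
random-walk-smoothed per-sample neighborhood abundances on a cell kNN
graph, with covariate residualization, a permutation global test and a
permutation-FDR cell mask.  Clinical stages include Kruskal–Wallis/Dunn
comparisons, Spearman screens with BH FDR, multivariable linear/logistic
models, repeated cross-validated elastic-net attribution, linear
mixed-model trends, and the week-52 renal-response rules (complete /
partial / none, evaluable iff baseline UPCR ≥ 1 g/g).

The real cohort behind this design is controlled-access, so the package
ships a synthetic-cohort generator (`cytostrat.synthetic`) that plants the
group structure — IFN-marker shifts in G1, cytotoxic/B-cell/neutrophil
expansions in G2, proliferating subsets in both, batch effects, and
clinical outcomes coupled to group (planted complete-response odds ratio
8.5 for G2, marginal rates 28 %/24 %/48 %) — with full ground truth for
parameter-recovery testing.  See `docs/methods.md` for the models and all
defaults.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from cytostrat.io import RunConfig, run_pipeline

cfg = RunConfig(master_seed=1, n_controls=20, n_per_group=20,
                cells_per_sample=300, restarts=20, n_perms=200)
res = run_pipeline(cfg, "demo_run")

print(res.assignment.groups.value_counts().to_string())
ln = res.metadata.loc[res.elevated.index, "disease"] == "LN"
print(f"IFN-elevated LN samples: {100*res.elevated[ln].mean():.1f}%  "
      f"(threshold {res.manifest['ifn_threshold']:.2f})")
ari = adjusted_rand_score(res.assignment.groups,
                          res.truth.sample_group.loc[res.assignment.groups.index])
print(f"ARI vs planted groups:   {ari:.2f}")
print(f"LN vs control neighborhood-DA p: {res.nda_global_p:.4f}")
```

prints (seed 1, ~25 s on one CPU):

```
G0    40
G1    22
G2    18
IFN-elevated LN samples: 66.7%  (threshold 4.81)
ARI vs planted groups:   0.95
LN vs control neighborhood-DA p: 0.0050
```

The 80 samples (20 controls + 60 LN) split into a control-anchored G0
(all 20 controls plus the 20 control-like LN samples), an IFN-high G1 and a
cytotoxic-enriched G2; the anchored labels agree with the planted truth at
ARI 0.95, two thirds of LN samples exceed the cohort-derived IFN elevation
threshold (G1 and G2 essentially always, control-like LN essentially
never), and the neighborhood test flags the LN-vs-control composition shift
at the permutation floor for 200 permutations.  `demo_run/` holds the
abundance matrix, scores, group assignments, PCA, clinical table,
response calls and a manifest with per-stage seeds and output hashes.

A thin CLI wraps the same stages:

```bash
cytostrat simulate --out cohort/ --seed 1      # FCS 3.1 files + CSV tables
cytostrat run --out run/ --seed 1              # full pipeline
cytostrat respond --clinical cohort/clinical.csv --out calls.csv
```

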