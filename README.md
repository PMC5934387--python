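# modulebayes

Expression-based disease classification from **coexpression-module
eigengenes** and an ensemble of **consensus discrete Bayesian networks**.

The package addresses a recurring problem in transcriptomics: a classifier
built on a few hundred samples cannot learn a model over thousands of
individual genes, and single-gene signatures transfer poorly between
profiling platforms (e.g. microarray to RNA-seq). The approach implemented
here compresses the transcriptome into a handful of robust features before
any supervised learning happens:

1. **Modules.** On the positive-class training samples, genes are linked by
   the soft-thresholded similarity `a_ij = |cor(x_i, x_j)|^β` (β chosen so
   the network approximates scale-free topology), pairwise adjacency is
   augmented with shared-neighbour structure through the unsigned
   topological overlap matrix `TOM_ij = (Σ_u a_iu a_uj + a_ij) /
   (min(k_i, k_j) + 1 − a_ij)`, and average-linkage clustering on `1 − TOM`
   partitions genes into modules (small clusters fall into module 0 and are
   excluded).
2. **Eigengenes.** Each module is summarised by its eigengene: the first
   principal component of the module's z-scored submatrix, estimated after
   oversampling both classes to near-equal representation (factors 9/11
   reproduce the reference class sizes 202/164 → 1,818/1,804 rows). Because
   genes are standardized, a trained eigengene can be *projected* onto any
   dataset sharing gene identifiers — per-gene affine changes of scale
   cancel, which is what makes cross-platform prediction work.
3. **Bayesian networks.** Eigengenes are discretized into three levels
   (Hartemink's mutual-information-preserving merging), and a binary
   `Effect` node encodes the disease class, blacklisted from having
   children. Structures are learned by hill climbing on the BDe score over
   bootstrap resamples; the top-scoring third of the bootstrap networks is
   averaged into a consensus DAG (majority-arc rule), whose conditional
   probability tables are fitted as Dirichlet posterior means. Since
   `Effect` has no children, its Markov blanket is exactly its parents and
   prediction reduces to a CPT lookup (a likelihood-weighting sampler is
   provided and agrees).
4. **Ensemble.** Five such models, each trained on 4/5 of the samples
   (subsampling without replacement), classify new samples by majority
   vote; the same five models are the 5-fold cross-validation models.

A synthetic-data module generates latent-factor expression data with
planted modules, class-linked factor shifts, probe-level multi-mapping and
a monotone platform transform, so the whole pipeline is testable without
any external download.

## Worked example

```python
from modulebayes import (
    RunConfig, generate_expression, generate_from_truth,
    train_from_expression, predict, performance,
)

# 10 planted modules of 30 genes, two shifted between classes (d = 2)
x, labels, truth = generate_expression(seed=0)
cfg = RunConfig(seed=0)
cfg.bn.R = 100                      # bootstrap networks per ensemble model
ensemble, modules, eigen = train_from_expression(x, labels, cfg)
print("modules:", modules.sizes)
print("Effect parents, model 1:", ensemble.bn_models[0].parents["Effect"])

x_new, y_new = generate_from_truth(truth, 200, 200, seed=42, prefix="t")
result = predict(ensemble, x_new)
report = performance(result["majority"].to_numpy(), y_new.to_numpy(),
                     scores=result["posterior"].to_numpy())
print(f"accuracy {report.accuracy:.3f}  precision {report.precision:.3f}  "
      f"recall {report.recall:.3f}  AUC {report.auc:.3f}")
```

Output:

```
modules: {1: 30, 2: 30, 3: 30, 4: 30, 5: 30, 6: 30, 7: 30, 8: 30, 9: 30, 10: 30}
Effect parents, model 1: ('M1', 'M2')
accuracy 0.895  precision 0.925  recall 0.860  AUC 0.961
```

All ten planted modules are recovered exactly; the two class-linked
modules (and only those) become parents of the `Effect` node; and 200+200
fresh samples from the same ground truth are classified at roughly the
optimum attainable for this effect size once the eigengenes are reduced to
three levels each (the continuous Bayes accuracy at a two-module shift of
d = 2 is ≈ 0.92).

## Command line

Every stage is also a subcommand of the `modulebayes` console script:
`simulate`, `preprocess` (moderated-t ranking, top-fraction filter, probe →
gene collapsing), `modules`, `eigengenes`, `learn` (one consensus network),
`train` (the full ensemble), `predict`, and `cv`. All commands accept
`--seed` (or a `key = value` TOML config via `-c`) and log their effective
configuration; identical seeds give identical outputs.

```sh
modulebayes simulate --n-pos 150 --n-neg 150 --seed 5 -o sim/
modulebayes train --expr sim/expression.tsv --labels sim/labels.tsv --seed 5 -o ensemble.json
modulebayes predict --model ensemble.json --expr sim/expression.tsv -o predictions.tsv
```

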