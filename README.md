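# omibench

Graph- and kernel-based multi-omics data-integration classifiers for binary
traits, with the full benchmarking protocol used to compare them.

## The problem

A clinical study often measures several omics layers — gene expression,
miRNA, methylation, proteomics — on the same patients, together with a
binary phenotype (case/control, receptor status, invasion status). No
single layer tells the whole story, and the layers live on incompatible
scales, so integration methods first map each source to a common
*sample-by-sample* representation (a similarity graph or a kernel matrix)
and then learn how to combine the sources. `omibench` implements seven such
integrators behind one interface, plus the evaluation designs needed to
compare them fairly, for anyone benchmarking integration strategies or
applying them to processed omics matrices.

## The seven integrators

Graph-based (transductive: test samples sit in the graph as unlabelled
nodes with `y_i = 0`):

1. **Graph semi-supervised learning** — per-source truncated-correlation
   graphs; scores minimise `||f − y||² + c·fᵀLf` with `L = D − W`; solved by
   `f = (I + cL)⁻¹y`; multiple networks are combined by convex weights α on
   the simplex `{α ≥ 0, Σα ≤ c}` minimising `yᵀ(I + Σα_k L_k)⁻¹y`; labels
   from the median cut-off rule.
2. **Graph sharpening** — directed edge removal (unlabelled→labelled and
   between opposite labels) before propagation;
   `f = [I + ½Σα_k(L_k + L_kᵀ)]⁻¹y`.
3. **Composite association network** — per-source weight matrices regressed
   onto a label-derived three-valued target network
   (`Ωα ≈ vec(T)`, normal equations, negative weights zeroed, uniform
   fallback), then single-network propagation with `c = 1`.
4. **Bayesian network** — per-source feature filtering (Bonferroni t-tests),
   signed standardised sum scores, quartile binning, optional dependence
   edges at |within-class correlation| > 0.3, and classification by the
   posterior odds ratio `Odd_post = Odd_prior · Π p(v|y=+1)/p(v|y=−1) > 1`.

Kernel-based (inductive):

5. **Multiple-kernel (SDP) SVM** — 1-norm soft-margin SVM whose kernel
   `K = Σμ_i K_i` is learned jointly with the dual via a QCQP with a trace
   budget `trace(Σμ_i K_i) = c` (c = training size); μ are the quadratic
   constraints' Lagrange multipliers.
6. **Relevance vector machine** — sparse Bayesian kernel classifier
   (type-II ML with a Laplace approximation); one RVM per source;
   per-source probabilities averaged and cut at 0.5.
7. **AdaBoost RVM** — boosted RVMs on weighted subsamples with
   `α_t = ½ln((1−ε_t)/ε_t)`, rounds with `ε_t ≥ 0.5` skipped, sample
   weights renormalised each round.

The evaluation module provides the confusion metrics (accuracy, F1,
sensitivity, specificity), rank-based AUC, repeated stratified 75/25
hold-out, leave-cluster-out cross-validation for family data, percentile
bootstrap 95% CIs over runs, and exact-ratio class-imbalance subsampling.
A synthetic multi-omics study generator with controllable per-source signal,
imbalance and family structure makes every method testable end to end.

## Worked example

```python
from omibench import (SimulationSpec, SourceSpec, generate_study,
                      repeated_holdout, make_algorithms)

spec = SimulationSpec(
    n_samples=120,
    sources=[SourceSpec(n_features=100, n_informative=20,
                        effect_size=1.5, name="expression"),
             SourceSpec(n_features=800, n_informative=0, name="methylation")],
    class_balance=0.5,
    seed=11,
)
study = generate_study(spec)
algorithms = make_algorithms(
    ["graph_ssl", "composite_network", "bayes_net", "sdp_svm", "rvm"],
    composite_network={"convention": "attraction"},
)
report = repeated_holdout(study, algorithms, n_runs=5, seed=0)
for algo, metrics in report.summary().items():
    auc = metrics["auc"]
    print(f"{algo:20s} AUC {auc['mean']:.3f}  "
          f"95% CI [{auc['ci95'][0]:.3f}, {auc['ci95'][1]:.3f}]")
```

prints

```
graph_ssl            AUC 1.000  95% CI [1.000, 1.000]
composite_network    AUC 1.000  95% CI [1.000, 1.000]
bayes_net            AUC 1.000  95% CI [1.000, 1.000]
sdp_svm              AUC 1.000  95% CI [1.000, 1.000]
rvm                  AUC 0.983  95% CI [0.961, 0.999]
```

Twenty informative features at 1.5 sd separation are an easy problem for
every integrator, so the AUCs saturate; the interest is in how each method
finds the signal (and how it weights the pure-noise methylation source —
inspect `algorithms["composite_network"].last_weights.alpha` or the SDP-SVM
`mu` to see). Harder regimes come from lowering `effect_size`,
`n_informative` or `n_samples`.

The same workflow is available from the shell:

```bash
omibench simulate  --config sim.yaml   --out data/
omibench benchmark --config bench.yaml --out report/
```

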