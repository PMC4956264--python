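# ppinet

Supervised protein–protein interaction network inference with kernel
methods, built for the cross-species transfer setting: train on one
species' known interactions, predict another species' network from
sequence-derived features.

Components:

- **kernels** — feature tables, interaction networks, kernel matrices;
  linear kernels, kernel centering, graph diffusion kernels
  `exp(-beta * L)`, centered kernel-target alignment.
- **pairwise** — link prediction as binary classification on protein
  pairs: DRCT / TPPK / MLPK pair kernels and a precomputed-kernel SVM.
- **ok3** — output kernel trees: CART-style induction maximizing
  kernel-space variance reduction, forest ensembles, pair scores from leaf
  co-membership.
- **iokr** — input–output kernel regression, supervised (kernel ridge) and
  semi-supervised (ridge + diffusion smoothness over labeled and unlabeled
  inputs), with closed-form dual solutions certified against numerical
  minimization.
- **mkl** — multiple kernel learning: uniform weights, independent
  alignment (ALIGN), joint alignment maximization via nonnegative QP
  (ALIGNF), and l_p-norm penalized alignment with path following in p.
- **seqsim** — synthetic benchmarks: BLOSUM-derived substitution models,
  sequence perturbation at the four standard levels (70% / BLOSUM30,
  60% / BLOSUM40, 38% / BLOSUM62, 20% / BLOSUM80), Smith–Waterman percent
  identity, and a module-structured transfer benchmark generator.
- **evaluation** — confusion-matrix metrics, ROC / PR curves with
  AUROC / AUPR, node-wise cross-validation (only test×test pairs are
  evaluated).
- **netvalidate** — mean absolute expression correlation over predicted
  edges with a degree-preserving rewiring permutation test.
- **io / cli / workflow** — FASTA/TSV/JSON I/O and the end-to-end
  transfer command.

## CLI

```sh
ppinet simulate --n-proteins 160 --n-modules 16 --seed 0 --out bench/
ppinet kernels  --features bench/features.tsv --network bench/edges.tsv --out kernels/
ppinet fit      --features bench/features.tsv --network bench/edges.tsv \
                --method alignf --out weights.tsv
ppinet predict  --source-features bench/features.tsv --source-network bench/edges.tsv \
                --target-features bench/features.tsv --learner iokr-semi \
                --mkl-method pnorm --out pred/
ppinet evaluate --scores pred/ranked_pairs.tsv --network bench/edges.tsv --out eval/
ppinet validate --network bench/edges.tsv --expression expr.tsv \
                --permutations 1000 --seed 0 --out validation.json
```

## Notes

- BLOSUM30/40/62/80 matrices are packaged in NCBI text format under
  `src/ppinet/data/`.
- All randomized operations take explicit seeds; synthetic benchmarks are
  byte-reproducible from their seed.
- Pair-pair kernels are evaluated as lazy blocks — the full O(m^4)
  pair-kernel matrix is never materialized implicitly.
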