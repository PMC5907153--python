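# comodule

Joint identification and comparison of gene coexpression network modules
across two conditions.

## The problem

Two biological conditions — two cancer types, two tissues, treatment vs
control — each yield a gene coexpression network over the same gene
universe. Analysing each network separately and matching modules afterwards
is brittle: module boundaries shift, and a gene set that is densely wired in
one condition but silent in the other is easy to miss. `comodule` finds and
aligns modules in **both** networks *simultaneously*, so that shared modules
come out once and condition-specific (differential) modules are carried by
whichever network supports them.

## The model

For condition k ∈ {1, 2} let A_k be the symmetric 0/1 adjacency over the
same n genes, D_k the degree matrix and L_k = D_k − A_k the (unnormalized)
graph Laplacian. Module assignments S^k (genes × M cluster indicators) are
sought that minimise the combined ratio-cut / cluster-alignment objective

    min Σ_k Σ_m (S^k_m)ᵀ L_k S^k_m / (S^k_m)ᵀ S^k_m
        − β Σ_{k,l} Σ_m cos(S^k_m, S^l_m)

where β ≥ 0 weights the cross-network alignment term. Relaxing the
indicators (S̃ᵀS̃ = 2 I_M) turns this into an eigenproblem for the coupled
2n × 2n block matrix

    C = [ L₁      −β·I ]
        [ −β·I     L₂  ]

whose every eigenvalue is ≥ −β. The eigenvectors of the M smallest
eigenvalues embed the 2n vertex copies in M dimensions; agglomerative
clustering (complete linkage, rank-based Spearman-type distance) cuts the
embedding into M clusters; corresponding per-network clusters are merged by
union, split into connected components of the union graph, and size-filtered
(default [5, 800]). M can be fixed or chosen at the first big eigengap of
the spectrum of C.

Upstream, two cross-comparable networks are built from expression matrices:
pairwise Pearson correlation, Fisher z transform z = ½·ln((1+r)/(1−r)),
per-condition standardization of the z-scores, back-transform, and one hard
threshold at the pooled 99.5% quantile of |r|. Downstream, per-module
statistics (average degree d̄ = 2m/n, density D = d̄/(n−1)) and a Bernoulli
edge-probability t-test compare a module's wiring between conditions, and a
hypergeometric over-representation test with Benjamini–Hochberg adjustment
scores modules against user-supplied gene sets (GMT).

A synthetic-data module generates two-layer planted-partition graphs and
factor-model expression matrices with shared and differential modules, so
the whole pipeline is testable end to end without external data.

## Worked example

```bash
python examples/01_simulate_and_recover.py
```

prints

```
layer A: 100 genes, 398 edges
layer B: 100 genes, 437 edges
recovered 4 modules of sizes [25, 24, 30, 25]
five smallest eigenvalues of C: [-1.     0.188  0.414  0.863  1.   ]
adjusted Rand index vs planted truth: 0.973
```

Four modules of 25 genes were planted with intra-module edge probability
0.30 against a 0.02 background in both layers. The smallest eigenvalue of C
is exactly −β (the coupling bound); the next three small eigenvalues carry
the module structure, and the recovered union modules agree with the planted
partition almost perfectly (ARI 0.973; 1.0 would be exact recovery).

The other examples walk through network construction from expression data
(`02`), the per-module statistics table and the differential-module test
(`03`), gene-set over-representation (`04`), and the differential-expression
gene filter (`05`).

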