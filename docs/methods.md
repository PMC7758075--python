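# Methods

## Problem setting and assumptions

`lpiskf` scores unobserved lncRNA–protein pairs from a binary bipartite
adjacency matrix **A** (n lncRNAs × m proteins) under two assumptions that
define the whole model family: (i) similar lncRNAs tend to interact with
similar proteins and vice versa, so predictive signal lives in entity–entity
similarity kernels; (ii) unobserved pairs are *unlabeled*, not negative —
the model is semi-supervised, and evaluation treats never-observed pairs as
the negative background only at scoring time.

## Similarity kernels

Three kernels per entity space, all with entries in [0, 1]:

| kernel | axis | definition | symmetric |
|---|---|---|---|
| GIP | both | exp(−γ‖A_u−A_v‖²), γ = n/Σ‖A_i‖² (rows) or m/Σ‖A_j‖² (columns) | yes |
| expression | lncRNA | (1+ρ_uv)/2, Pearson ρ over the tissue panel; diagonal 0 | yes |
| alignment | protein | b(u,v)/b(u,u) from local-alignment bit scores; diagonal 0 | no |
| LNS | both | convex reconstruction weights over k nearest feature neighbors | no |

Notes and edge cases:

* The GIP bandwidth γ normalizes by the *mean* squared profile norm, so the
  kernel is invariant to entity count at fixed interaction density. An
  all-zero adjacency leaves γ undefined and is a hard error.
* Zero-variance (or imputed-missing) expression profiles have undefined
  correlation; their similarities are set to 0 — consistent with the
  kernel's diagonal-0 convention — with a warning.
* The alignment kernel is deliberately *not* symmetrized
  (b(u,v)/b(u,u) ≠ b(v,u)/b(v,v)); ratios above 1 (a cross-alignment
  outscoring a self-alignment) are clipped with a warning.
* Bit scores may be supplied as BLAST tabular output (best HSP per pair
  wins), or computed internally by Smith–Waterman local alignment
  (BLOSUM62, gap open 11 / extend 1) with raw scores converted to bits via
  the ungapped Karlin–Altschul constants λ = 0.3176, K = 0.134. The
  internal path keeps the package free of external binaries and is fully
  deterministic.
* Protein features are composition/transition/distribution (CTD)
  descriptors over four physicochemical 3-group partitions
  (hydrophobicity, van der Waals volume, polarity, polarizability),
  21 values each → 84-D by default. Published descriptions of this
  feature set sometimes quote other dimensionalities; the construction
  here is the standard 21-per-property CTD and the property set is
  configurable, so downstream behavior (LNS is dimension-agnostic) does
  not depend on the choice.
* LNS solves min_w ‖x_u − Σ_{v∈N(u)} w_v x_v‖² s.t. Σw = 1, w ≥ 0 over the
  k nearest neighbors (Euclidean, self excluded, distance ties broken by
  lower index). The nonnegative solve uses penalty-augmented NNLS (penalty
  10⁶ on the sum-to-one row), which handles degenerate neighbor sets
  (duplicated points) natively; the unconstrained-sign variant uses a Gram
  solve with ridge 10⁻⁶·trace added only when the Gram matrix is singular.
  Default k: ⌈n/10⌉ for lncRNAs, 3 for proteins, matching the fusion
  neighborhood scales.

## Similarity kernel fusion

Per space, with kernels s_q (q = 0 interaction, 1 expression/alignment,
2 sequence features):

1. **Column normalization** Θ_q(u,v) = s_q(u,v)/Σ_t s_q(t,v). Standalone
   use treats an all-zero column as an error; inside the fusion pipeline
   zero columns are kept at zero, because sparse asymmetric kernels (LNS)
   legitimately produce entities that nobody selects as a neighbor.
2. **kNN indicators** I_q: per row, the k most similar entities, self
   excluded, similarity ties broken toward the lower index (deterministic
   across platforms). Self-exclusion avoids mixing the GIP convention
   (diagonal 1) with the diagonal-0 kernels; it is configurable at the
   `knn_indicator` level.
3. **Neighbor normalization** Φ_q = row-normalized s_q∘I_q; a row whose k
   neighbors all have similarity 0 is a degenerate-kernel error.
4. **Cross-diffusion**, z synchronous rounds, all kernels updated from
   round-λ values:
   Θ_q(λ+1) = ½α Φ_q (Σ_{r≠q} Θ_r(λ)) Φ_qᵀ + ½(1−α) Σ_{r≠q} Θ_r(0).
   The update is implemented literally (the ½ prefactor is the 1/(K−1)
   average over the two other kernels; the generalization to K kernels
   replaces ½ accordingly). No re-normalization is applied between
   rounds; an optional flag could be added for experimentation but the
   default pathway is the literal iteration. z = 0 degenerates to the
   plain mean of the column-normalized kernels.
5. **Agreement mask** w(u,v) = 1 / 0 / 0.5 as all / none / some of the
   three indicators mark v a neighbor of u; S = (mean of diffused Θ) ∘ w.

Asymmetric inputs are fused as-is; symmetrization is deferred to the
predictor.

## Laplacian regularized least squares

The fused kernel is symmetrized, S ← (S+Sᵀ)/2 (configurable off), because
the D−S Laplacian and its [0, 2] spectrum require symmetry; then
L = D^(−1/2)(D−S)D^(−1/2) with D the diagonal of row sums (a zero row sum
is an error naming the entity). The per-space score matrix is the closed
form

    F_side = S (S + β L S)⁻¹ A,

equal to (I+βL)⁻¹A — the minimizer of ‖A−F‖²_F + β·tr(FᵀLF) — whenever S
is invertible; the tests assert both identities numerically. The protein-
space solve acts on Aᵀ and is transposed back (the only shape-consistent
reading of the two-space formulation). The linear system is solved by LU
factorization; if the reciprocal condition number falls below 10⁻¹², the
solve falls back to the Moore–Penrose pseudo-inverse and logs the
condition number. β = 0 returns A exactly for invertible S. The final
score is the blend F = δF_l + (1−δ)F_p.

Defaults: β_l = β_p = 2⁻³, δ = 0.8, α = 0.9/0.8 and z = 5 as above —
the published calibration of this model family; the neighborhood size
default is scale-aware (⌈n/10⌉ lncRNA / 3 protein, i.e. 99/3 at the
990×27 benchmark scale).

## Cross-validation protocols

Three 5-fold schemes: *pairwise* (positives partitioned, held-out
positives zeroed in the training adjacency), *novel-lncrna* and
*novel-protein* (entities partitioned, entire rows/columns zeroed). Fold
sizes differ by at most one; the partition is a seeded permutation.

Only the GIP kernels depend on A, so only they are recomputed per fold,
from the masked adjacency — held-out information is provably absent from
every A-derived kernel (asserted in the tests by perturbing the masked
cells and checking kernel invariance). Held-out entities in the novel
schemes have all-zero interaction profiles; their GIP similarities
exp(−γ‖0−A_v‖²) remain well-defined with γ from the training matrix.

Pooling: each positive is scored exactly once, in the fold where it is
held out. In the pairwise scheme the never-positive background is scored
in every fold and the five scores are averaged into one pooled value per
cell; in the novel schemes every cell of a held-out row/column is scored
exactly once. Training positives of the current fold are excluded from the
evaluation pool by default (`include_train_negatives` adds them as
negatives). Both the pooled AUROC and the per-fold mean are reported;
pooled is the headline.

Metrics: AUROC (Mann–Whitney, ties ½) and AUPR (precision–recall step
curve) via scikit-learn, validated in the tests against brute-force
pair-counting and step-curve oracles; precision/recall/F1 at the
F1-maximizing threshold (exhaustive scan over unique scores, ties toward
the lower threshold). Ranking for case-study-style output takes the k
best-scoring cells with no known interaction, ties broken by (row, column)
index.

## Synthetic data generator

The generator emulates the four input artifacts from one latent model so
that every similarity channel carries signal about the planted structure:
noisy one-hot cluster factors U, V; interactions thresholded from UVᵀ at
the target density then label-flipped at the noise rate; expression = a
random linear map of U plus Gaussian noise; sequences drawn from
per-cluster residue compositions (RNA base bias; amino-acid
hydrophobicity-group bias); bit scores high within and low between protein
clusters with asymmetric noise and maximal diagonal.

Default study conditions: 60 lncRNAs × 12 proteins, rank 3, density 0.15,
flip noise 0.02, 24 expression tissues, sequence lengths 150–400 nt /
80–200 aa — desk-scale sizes that keep the full pipeline and all tests in
seconds while leaving every stage non-trivial. A benchmark-scale preset
(990×27, ~4158 interactions) exists for scalability smoke tests.

What the generator does *not* emulate: real expression distributions
(counts, dropouts), realistic BLAST score statistics beyond rank
structure, homology families within clusters, or the extreme 990:27 axis
asymmetry of curated data in the default shape. Passing recovery tests
therefore demonstrate internal consistency of the pipeline on structured
data — not performance on any real interactome.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; identical seeds give bit-identical artifacts.
* kNN and ranking tie-breaks are by lower index after stable sorting, so
  results are platform-independent.
* Matrix TSV serialization uses full float repr and round-trip parsing;
  write-then-read reproduces matrices bit-exactly.
* Fused scores are clipped at 0 against negative round-off; kernels
  validate nonnegativity and finiteness on construction.

## Known limitations

* The alignment-kernel internal aligner scores all O(m²) protein pairs;
  for hundreds of proteins, precomputed BLAST tabular input is the
  intended path.
* The closed-form LapRLS solve is dense (O(n³)); the 990×27 scale runs in
  seconds, but orders of magnitude beyond that would need iterative
  solvers, which are out of scope.
* Expression, alignment and feature kernels are treated as
  adjacency-independent and computed once per cross-validation; if a
  user-supplied kernel secretly encodes interaction information, the
  leakage guarantees do not cover it.
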