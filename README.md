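# lpiskf

Prediction of lncRNA–protein interactions by **similarity kernel fusion
(SKF)** and **Laplacian regularized least squares (LapRLS)**.

Long non-coding RNAs act mostly through the proteins they bind, but the
experimentally verified interaction map is sparse: a typical curated
benchmark holds ~4000 interactions between ~1000 lncRNAs and a few dozen
proteins. `lpiskf` treats the problem as semi-supervised link prediction on
this bipartite network: every unobserved pair is scored, and the
highest-scoring unknown pairs are candidate interactions. The package is
aimed at computational biologists who want a transparent, fully tested
implementation of this model that runs end-to-end on synthetic data — no
database downloads required — and accepts their own interaction lists,
FASTA files, expression tables and BLAST bit-score tables.

## The model

Let **A** ∈ {0,1}^(n×m) be the adjacency matrix over n lncRNAs and m
proteins. Three similarity kernels are built per entity space:

* **Gaussian interaction-profile (GIP)** kernel on rows/columns of A:
  s(u,v) = exp(−γ‖A_u − A_v‖²), γ = n / Σᵢ‖A_i‖²;
* lncRNA **expression** similarity (1+ρ)/2 from Pearson correlation across
  a tissue panel, and protein **alignment** similarity b(u,v)/b(u,u) from
  pairwise local-alignment bit scores (asymmetric by construction);
* **linear neighborhood similarity (LNS)** on sequence features (4+16
  nucleotide/dinucleotide frequencies for RNA; 84-D
  composition/transition/distribution descriptors for proteins): each
  feature vector is optimally reconstructed as a convex combination of its
  k nearest neighbors, and the weights are the similarities.

SKF fuses the three kernels per space: column-normalize each kernel
(Θ_q), row-normalize its restriction to each entity's k nearest neighbors
(Φ_q), then iterate the cross-diffusion

    Θ_q ← ½ α Φ_q (Σ_{r≠q} Θ_r) Φ_qᵀ + ½ (1−α) Σ_{r≠q} Θ_r(0)

for z rounds, average the three results, and mask by the neighborhood
agreement weight w ∈ {0, ½, 1}. LapRLS then scores all pairs in closed
form in each space,

    F_side = S (S + β L S)⁻¹ A,      L = D^(−1/2) (D − S) D^(−1/2),

and blends F = δ F_l + (1−δ) F_p. Defaults follow the published
calibration: α = 0.9 (lncRNA) / 0.8 (protein), k = n/10 (lncRNA, 99 at
benchmark scale) / 3 (protein), z = 5, β_l = β_p = 2⁻³, δ = 0.8.

## Worked example

```python
from lpiskf import LPISKF, SyntheticConfig, generate_dataset

data = generate_dataset(SyntheticConfig(seed=1))   # 60 lncRNAs x 12 proteins
results = LPISKF.from_synthetic(data).fit()
print(results.summary())
```

```
LPI-SKF: similarity kernel fusion + Laplacian RLS
==================================================
lncRNAs                 60
proteins                12
known interactions      117
SKF lncRNA (alpha,k,z)  (0.9, 6, 5)
SKF protein (alpha,k,z) (0.8, 3, 5)
LapRLS beta_l, beta_p   0.125, 0.125
blend delta             0.8
mean score (known)      0.9592
mean score (unknown)    0.0076
top 5 novel predictions:
  LNC0045      PROT005    0.0921
  LNC0031      PROT001    0.0899
  LNC0044      PROT008    0.0720
  LNC0000      PROT006    0.0705
  LNC0044      PROT001    0.0679
```

Known interactions score near 1 and the unknown background near 0; the
"top novel predictions" are the unobserved pairs the model ranks highest —
the candidates one would take to validation. Cross-validation with
leakage-safe kernel recomputation (the GIP kernels are rebuilt from the
masked adjacency inside every fold):

```python
report = LPISKF.from_synthetic(data).cross_validate(scheme="pairwise", seed=0)
print(f"AUROC {report.auroc:.3f}  AUPR {report.aupr:.3f}")
# AUROC 0.929  AUPR 0.840
```

`scheme="novel-lncrna"` / `"novel-protein"` hold out whole entities
instead of single pairs, emulating prediction for molecules with no known
partner.

The same pipeline is available from the shell:

```bash
lpiskf simulate --seed 1 --outdir data
lpiskf cv --indir data --scheme pairwise --outdir cv_out
lpiskf rank --scores scores/scores.tsv --pairs data/pairs.tsv --top 20
```

plus `similarities`, `fuse`, `predict` and `gridsearch` subcommands for
the individual stages.

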