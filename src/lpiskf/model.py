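"""Model/Results front end tying the pipeline together.

:class:`LPISKF` is constructed from a bipartite interaction dataset plus the
adjacency-independent side information (expression, sequence-feature and
alignment kernels); ``fit()`` computes the interaction-profile kernels,
fuses all kernels per entity space, solves the Laplacian-regularized least
squares system and returns an :class:`LPISKFResults` carrying the score
matrix, the fusion diagnostics and ranking/summary helpers.

    >>> from lpiskf import LPISKF, SyntheticConfig, generate_dataset
    >>> data = generate_dataset(SyntheticConfig(seed=1))
    >>> res = LPISKF.from_synthetic(data).fit()
    >>> res.top_pairs(3)          # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import InteractionDataset
from .evaluation import (EvalReport, entity_folds, pair_folds, run_cv,
                         top_k_predictions)
from .fusion import FusionState, SkfParams, fuse_kernels
from .laprls import LaprlsParams, PredictionMatrix, predict_bipartite
from .similarity import (SimilarityKernel, alignment_similarity,
                         expression_similarity, gip_kernel,
                         lncrna_nucleotide_features, lns_similarity,
                         pairwise_bitscores, protein_ctd_features)
from .synthetic import (SyntheticConfig, SyntheticData, generate_dataset,
                        mask_positives)


def default_skf_params(dim: int, axis: str) -> SkfParams:
    """Scale-aware fusion defaults.

    alpha = 0.9 (lncRNA) / 0.8 (protein); neighborhood size one tenth of the
    lncRNA count (99 at the 990-lncRNA benchmark scale) and 3 for proteins,
    clipped below the dimension; z = 5 rounds.
    """
    if axis == "lncrna":
        return SkfParams(alpha=0.9, k=min(max(1, math.ceil(dim / 10)), dim - 1), z=5)
    return SkfParams(alpha=0.8, k=min(3, dim - 1), z=5)


def planted_recovery_scores(cfg: SyntheticConfig, mask_fraction: float = 0.2,
                            mask_seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Hide a fraction of a synthetic study's interactions, refit, score the unknowns.

    Returns ``(scores, labels)`` over all cells unknown to the trained model:
    label 1 for the hidden interactions, 0 for the never-positive cells.  The
    central self-check of the package — the pipeline must rank the hidden
    interactions far above the unknown background.
    """
    data = generate_dataset(cfg)
    train, held_out = mask_positives(data.dataset, mask_fraction,
                                     seed=cfg.seed if mask_seed is None else mask_seed)
    masked = SyntheticData(train, data.lncrna_sequences, data.protein_sequences,
                           data.expression, data.bitscores)
    results = LPISKF.from_synthetic(masked).fit()
    unknown = train.A == 0
    labels = np.zeros_like(train.A)
    for i, j in held_out:
        labels[i, j] = 1.0
    return results.prediction.F[unknown], labels[unknown]


class LPISKF:
    """Semi-supervised lncRNA-protein interaction predictor.

    Parameters
    ----------
    dataset
        Identifier lists and the binary adjacency matrix.
    lncrna_kernels, protein_kernels
        The adjacency-independent similarity kernels per space (canonically
        expression + sequence-feature for lncRNAs, alignment +
        sequence-feature for proteins).  The interaction-profile kernel is
        always computed from the (training) adjacency at fit time and
        prepended, so cross-validation can recompute it per fold.
    skf_lncrna, skf_protein
        Fusion parameters per space; scale-aware defaults when omitted.
    laprls
        Regularization/blending parameters (beta_l = beta_p = 2**-3,
        delta = 0.8 by default).
    """

    def __init__(self, dataset: InteractionDataset,
                 lncrna_kernels: list[SimilarityKernel],
                 protein_kernels: list[SimilarityKernel],
                 skf_lncrna: SkfParams | None = None,
                 skf_protein: SkfParams | None = None,
                 laprls: LaprlsParams | None = None):
        for kern in lncrna_kernels:
            if kern.dim != dataset.n:
                raise ValueError("lncRNA kernel dimension does not match dataset")
        for kern in protein_kernels:
            if kern.dim != dataset.m:
                raise ValueError("protein kernel dimension does not match dataset")
        self.dataset = dataset
        self.lncrna_kernels = list(lncrna_kernels)
        self.protein_kernels = list(protein_kernels)
        self.skf_lncrna = skf_lncrna or default_skf_params(dataset.n, "lncrna")
        self.skf_protein = skf_protein or default_skf_params(dataset.m, "protein")
        self.laprls = laprls or LaprlsParams()

    @classmethod
    def from_synthetic(cls, data: SyntheticData, lns_k_lncrna: int | None = None,
                       lns_k_protein: int | None = None, **kwargs) -> "LPISKF":
        """Assemble the model from a synthetic study bundle."""
        expr = expression_similarity(data.expression)
        lns_l = lns_similarity(lncrna_nucleotide_features(data.lncrna_sequences),
                               k=lns_k_lncrna)
        align = alignment_similarity(data.bitscores)
        lns_p = lns_similarity(protein_ctd_features(data.protein_sequences),
                               k=lns_k_protein)
        return cls(data.dataset, [expr, lns_l], [align, lns_p], **kwargs)

    @classmethod
    def from_files(cls, pairs_path, lncrna_fasta, protein_fasta, expression_path,
                   bitscore_path=None, **kwargs) -> "LPISKF":
        """Assemble the model from the four on-disk artifacts.

        When no precomputed bit-score table is given, all-vs-all local
        alignment bit scores are computed from the protein sequences.
        """
        from . import datasets as dio

        pairs, _ = dio.read_interaction_pairs(pairs_path)
        dataset = dio.build_adjacency(pairs)
        rna = dio.read_fasta(lncrna_fasta, alphabet="rna")
        prot = dio.read_fasta(protein_fasta, alphabet="protein")
        expression = dio.read_expression_table(expression_path)
        # Align artifact orderings to the dataset's frozen id orders.
        rna = type(rna)({i: rna[i] for i in dataset.lncrna_ids}, axis="lncrna", alphabet="rna")
        prot = type(prot)({j: prot[j] for j in dataset.protein_ids}, axis="protein",
                          alphabet="protein")
        order = [expression.ids.index(i) for i in dataset.lncrna_ids]
        expression = type(expression)(list(dataset.lncrna_ids), expression.values[order],
                                      tissues=expression.tissues,
                                      imputed_ids=expression.imputed_ids)
        if bitscore_path is not None:
            bits = dio.read_bitscore_table(bitscore_path, protein_ids=dataset.protein_ids)
        else:
            bits = pairwise_bitscores(prot)
        data = SyntheticData(dataset, rna, prot, expression, bits)
        return cls.from_synthetic(data, **kwargs)

    def fit(self) -> "LPISKFResults":
        """Fuse kernels and solve the closed-form scoring system."""
        gip_l = gip_kernel(self.dataset, "lncrna")
        gip_p = gip_kernel(self.dataset, "protein")
        fused_l, state_l = fuse_kernels([gip_l, *self.lncrna_kernels], self.skf_lncrna)
        fused_p, state_p = fuse_kernels([gip_p, *self.protein_kernels], self.skf_protein)
        prediction = predict_bipartite(fused_l, fused_p, self.dataset, self.laprls)
        return LPISKFResults(model=self, prediction=prediction,
                             fused_lncrna=fused_l, fused_protein=fused_p,
                             fusion_state_lncrna=state_l, fusion_state_protein=state_p)

    def cross_validate(self, scheme: str = "pairwise", n_folds: int = 5,
                       seed: int = 0, include_train_negatives: bool = False) -> EvalReport:
        """Run one of the three CV protocols with leakage-safe kernel recomputation."""
        if scheme == "pairwise":
            plan = pair_folds(self.dataset, n_folds, seed)
        elif scheme in ("novel-lncrna", "novel-protein"):
            plan = entity_folds(self.dataset, scheme.split("-")[1], n_folds, seed)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        return run_cv(self.dataset, self.lncrna_kernels, self.protein_kernels,
                      self.skf_lncrna, self.skf_protein, self.laprls, plan,
                      include_train_negatives=include_train_negatives)


@dataclass
class LPISKFResults:
    """Fitted scores plus fusion diagnostics and ranking helpers."""

    model: LPISKF
    prediction: PredictionMatrix
    fused_lncrna: SimilarityKernel
    fused_protein: SimilarityKernel
    fusion_state_lncrna: FusionState = field(repr=False, default=None)
    fusion_state_protein: FusionState = field(repr=False, default=None)

    @property
    def scores(self) -> pd.DataFrame:
        """The blended score matrix as an id-labelled DataFrame."""
        ds = self.model.dataset
        return pd.DataFrame(self.prediction.F, index=ds.lncrna_ids, columns=ds.protein_ids)

    def top_pairs(self, k: int = 20) -> pd.DataFrame:
        """The k best-scoring pairs not already known (the case-study ranking)."""
        ds = self.model.dataset
        rows = top_k_predictions(self.prediction.F, ds.A, k,
                                 lncrna_ids=ds.lncrna_ids, protein_ids=ds.protein_ids)
        return pd.DataFrame(rows, columns=["lncrna", "protein", "score"])

    def summary(self) -> str:
        ds = self.model.dataset
        sl, sp, lp = self.model.skf_lncrna, self.model.skf_protein, self.model.laprls
        F = self.prediction.F
        known = ds.A == 1
        lines = [
            "LPI-SKF: similarity kernel fusion + Laplacian RLS",
            "=" * 50,
            f"lncRNAs                 {ds.n}",
            f"proteins                {ds.m}",
            f"known interactions      {int(ds.A.sum())}",
            f"SKF lncRNA (alpha,k,z)  ({sl.alpha}, {sl.k}, {sl.z})",
            f"SKF protein (alpha,k,z) ({sp.alpha}, {sp.k}, {sp.z})",
            f"LapRLS beta_l, beta_p   {lp.beta_l:.6g}, {lp.beta_p:.6g}",
            f"blend delta             {lp.delta}",
            f"mean score (known)      {F[known].mean():.4f}" if known.any() else "",
            f"mean score (unknown)    {F[~known].mean():.4f}" if (~known).any() else "",
        ]
        top = self.top_pairs(5)
        lines.append("top 5 novel predictions:")
        for _, row in top.iterrows():
            lines.append(f"  {row.lncrna:<12} {row.protein:<10} {row.score:.4f}")
        return "\n".join(x for x in lines if x)
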