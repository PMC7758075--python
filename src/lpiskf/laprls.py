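"""Laplacian regularized least squares (LapRLS) scoring of the bipartite network.

Scores are obtained in closed form in each entity space,

    F_side = S (S + beta * L S)^(-1) A,

where S is the fused similarity, L its normalized graph Laplacian and A the
(training) adjacency; the lncRNA-space and protein-space predictions are then
blended, F = delta * F_l + (1 - delta) * F_p.  When S is invertible the
closed form equals (I + beta L)^(-1) A, the minimizer of
||A - F||_F^2 + beta * tr(F^T L F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datasets import InteractionDataset
from .similarity import SimilarityKernel

logger = logging.getLogger(__name__)

_RCOND_LIMIT = 1e-12


@dataclass
class LaprlsParams:
    """Regularization weights per space and the convex combination weight."""

    beta_l: float = 2.0 ** -3
    beta_p: float = 2.0 ** -3
    delta: float = 0.8

    def __post_init__(self) -> None:
        if self.beta_l < 0 or self.beta_p < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")


@dataclass
class PredictionMatrix:
    """Final and per-space score matrices plus the Laplacians used."""

    F: np.ndarray
    F_l: np.ndarray
    F_p: np.ndarray
    L_l: np.ndarray
    L_p: np.ndarray
    lncrna_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        for name in ("F", "F_l", "F_p"):
            val = getattr(self, name)
            if not np.isfinite(val).all():
                raise ValueError(f"{name} contains non-finite entries")


def normalized_laplacian(kernel: SimilarityKernel | np.ndarray,
                         symmetrize: bool = True) -> np.ndarray:
    """Symmetric normalized graph Laplacian L = D^(-1/2) (D - S) D^(-1/2).

    The kernel is symmetrized first by default (fused kernels inherit
    asymmetry from the alignment and LNS sources, but Laplacian smoothness
    and the [0, 2] spectrum need a symmetric S).  D is the diagonal matrix of
    row sums; zero row sums are a hard error naming the entity.
    """
    S = kernel.values if isinstance(kernel, SimilarityKernel) else np.asarray(kernel, dtype=float)
    ids = kernel.ids if isinstance(kernel, SimilarityKernel) else None
    if symmetrize:
        S = (S + S.T) / 2.0
    d = S.sum(axis=1)
    if (d <= 0).any():
        which = [ids[i] if ids is not None else i for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"zero row sum in similarity for entities {which}: Laplacian undefined")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(S.shape[0]) - inv_sqrt[:, None] * S * inv_sqrt[None, :]
    return (L + L.T) / 2.0


def laprls_solve(kernel: SimilarityKernel | np.ndarray, L: np.ndarray,
                 A: np.ndarray, beta: float) -> np.ndarray:
    """Closed-form per-space solve F = S (S + beta L S)^(-1) A.

    Uses an LU factorization of (S + beta L S); falls back to the
    pseudo-inverse when the system is numerically singular (reciprocal
    condition below 1e-12), logging the condition number.
    """
    S = kernel.values if isinstance(kernel, SimilarityKernel) else np.asarray(kernel, dtype=float)
    A = np.asarray(A, dtype=float)
    M = S + beta * (L @ S)
    try:
        cond = np.linalg.cond(M)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or 1.0 / cond < _RCOND_LIMIT:
        logger.warning("LapRLS system singular (cond=%.3g); using pseudo-inverse", cond)
        return S @ (np.linalg.pinv(M) @ A)
    return S @ scipy.linalg.solve(M, A)


def predict_bipartite(S_l: SimilarityKernel, S_p: SimilarityKernel,
                      dataset: InteractionDataset,
                      params: LaprlsParams | None = None,
                      symmetrize: bool = True) -> PredictionMatrix:
    """Score all lncRNA-protein pairs from both similarity spaces.

    The lncRNA-space solve consumes A directly; the protein-space solve acts
    on A^T (the only shape-consistent reading) and the result is transposed
    back before blending with weight delta.
    """
    if params is None:
        params = LaprlsParams()
    A = dataset.A
    if S_l.dim != dataset.n or S_p.dim != dataset.m:
        raise ValueError("similarity dimensions do not match the dataset")
    logger.info("LapRLS with beta_l=%g beta_p=%g delta=%g", params.beta_l, params.beta_p, params.delta)
    L_l = normalized_laplacian(S_l, symmetrize=symmetrize)
    L_p = normalized_laplacian(S_p, symmetrize=symmetrize)
    F_l = laprls_solve(S_l, L_l, A, params.beta_l)
    F_p = laprls_solve(S_p, L_p, A.T, params.beta_p).T
    F = params.delta * F_l + (1.0 - params.delta) * F_p
    return PredictionMatrix(F=F, F_l=F_l, F_p=F_p, L_l=L_l, L_p=L_p,
                            lncrna_ids=list(dataset.lncrna_ids),
                            protein_ids=list(dataset.protein_ids))
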