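"""Similarity kernel fusion (SKF).

Per entity space, three similarity kernels are merged by an iterative
cross-diffusion: each column-normalized kernel is propagated through the
k-nearest-neighbor-restricted versions of the *other* kernels, the results
are averaged, and finally masked by a weight matrix expressing how strongly
the three kernels agree on each neighborhood relation.

The pipeline, for kernels s_q (q = 0, 1, 2):

1. column normalization          Theta_q(u,v) = s_q(u,v) / sum_t s_q(t,v)
2. kNN indicators                I_q(u,v)     = 1 iff v in the k most similar to u
3. neighbor normalization        Phi_q(u,v)   = s_q I_q / row sum
4. z synchronous diffusion steps Theta_q <- a/2 * Phi_q (sum_{r!=q} Theta_r) Phi_q^T
                                            + (1-a)/2 * sum_{r!=q} Theta_r(0)
5. average                       Theta_bar = mean_q Theta_q(z)
6. agreement mask                w = 1 / 0.5 / 0 as all / some / none of the
                                 I_q mark (u,v) a neighbor; S = Theta_bar * w
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityKernel


@dataclass
class SkfParams:
    """Fusion parameters: diffusion weight alpha, neighborhood size k, rounds z."""

    alpha: float = 0.9
    k: int = 99
    z: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.z < 0:
            raise ValueError(f"z must be >= 0, got {self.z}")


@dataclass
class FusionState:
    """All intermediate fusion artifacts, kept for inspection and testing."""

    theta: list[np.ndarray]
    indicators: list[np.ndarray]
    phi: list[np.ndarray]
    theta_bar: np.ndarray
    weights: np.ndarray
    s_final: np.ndarray
    params: SkfParams = field(default_factory=SkfParams)


def column_normalize(values: np.ndarray, ids=None, on_zero_column: str = "error") -> np.ndarray:
    """Normalize each column to sum 1.

    ``on_zero_column='error'`` raises naming the entity of an all-zero column;
    ``'keep'`` leaves zero columns zero (used inside the fusion pipeline where
    sparse asymmetric kernels legitimately produce them).
    """
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        if on_zero_column == "error":
            which = [ids[j] if ids is not None else j for j in np.flatnonzero(zero)]
            raise ValueError(f"all-zero column(s) for entities {which}: cannot column-normalize")
        sums = np.where(zero, 1.0, sums)
    return values / sums[None, :]


def knn_indicator(values: np.ndarray, k: int) -> np.ndarray:
    """0/1 matrix marking, per row u, the k most similar entities (self excluded).

    Ties are broken deterministically toward the lower index.  Every row sums
    to exactly k.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < dimension {n}")
    I = np.zeros((n, n))
    idx = np.arange(n)
    for u in range(n):
        row = values[u].copy()
        row[u] = -np.inf  # exclude self
        order = np.lexsort((idx, -row))
        I[u, order[:k]] = 1.0
    return I


def neighbor_normalize(values: np.ndarray, indicator: np.ndarray, ids=None) -> np.ndarray:
    """Row-normalize the kernel restricted to each row's neighborhood.

    Phi(u,v) = s(u,v) I(u,v) / sum_t s(u,t) I(u,t); rows sum to 1, zero outside
    neighborhoods.  A row whose neighbors all have similarity 0 is degenerate.
    """
    masked = np.asarray(values, dtype=float) * np.asarray(indicator, dtype=float)
    sums = masked.sum(axis=1)
    zero = sums == 0
    if zero.any():
        which = [ids[u] if ids is not None else u for u in np.flatnonzero(zero)]
        raise ValueError(f"degenerate kernel: zero similarity to all k neighbors for {which}")
    return masked / sums[:, None]


def agreement_weights(indicators: list[np.ndarray]) -> np.ndarray:
    """Neighborhood agreement mask: 1 where all indicators agree positive,
    0 where all agree negative, 0.5 otherwise."""
    stack = np.stack([np.asarray(I, dtype=float) for I in indicators])
    total = stack.sum(axis=0)
    K = stack.shape[0]
    return np.where(total == K, 1.0, np.where(total == 0, 0.0, 0.5))


def skf_diffuse(thetas: list[np.ndarray], phis: list[np.ndarray],
                params: SkfParams) -> np.ndarray:
    """Run z synchronous cross-diffusion rounds and return the averaged kernel.

    Each kernel is updated from the round-lambda values of the *other*
    kernels; with the canonical three kernels the 1/(K-1) prefactor is the
    printed 1/2.  z = 0 returns the plain mean of the inputs.
    """
    K = len(thetas)
    if K < 2:
        raise ValueError("need at least two kernels to diffuse")
    shapes = {t.shape for t in thetas} | {p.shape for p in phis}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {shapes}")
    theta0 = [np.asarray(t, dtype=float).copy() for t in thetas]
    cur = [t.copy() for t in theta0]
    a = params.alpha
    for _ in range(params.z):
        nxt = []
        for q in range(K):
            sum_other = sum(cur[r] for r in range(K) if r != q)
            sum_other0 = sum(theta0[r] for r in range(K) if r != q)
            nxt.append(a / (K - 1) * (phis[q] @ sum_other @ phis[q].T)
                       + (1.0 - a) / (K - 1) * sum_other0)
        cur = nxt
    return sum(cur) / K


def fuse_kernels(kernels: list[SimilarityKernel], params: SkfParams) -> tuple[SimilarityKernel, FusionState]:
    """Full fusion of (canonically three) kernels on one axis into the adjusted similarity.

    Returns the final kernel S = Theta_bar * w together with the complete
    :class:`FusionState` for inspection.
    """
    axes = {kern.axis for kern in kernels}
    dims = {kern.dim for kern in kernels}
    if len(axes) != 1 or len(dims) != 1:
        raise ValueError("all kernels must share one axis and dimension")
    ids = kernels[0].ids
    theta = [column_normalize(k.values, ids=ids, on_zero_column="keep") for k in kernels]
    indicators = [knn_indicator(k.values, params.k) for k in kernels]
    phi = [neighbor_normalize(k.values, I, ids=ids) for k, I in zip(kernels, indicators)]
    theta_bar = skf_diffuse(theta, phi, params)
    w = agreement_weights(indicators)
    s_final = theta_bar * w
    s_final = np.clip(s_final, 0.0, None)
    fused = SimilarityKernel(s_final, list(ids), axis=kernels[0].axis, source="fused")
    state = FusionState(theta=theta, indicators=indicators, phi=phi,
                        theta_bar=theta_bar, weights=w, s_final=s_final, params=params)
    return fused, state
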