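"""The six similarity kernels.

Per entity space three kernels are built:

* lncRNAs — Gaussian interaction-profile (GIP) kernel on adjacency rows,
  Pearson expression similarity, and linear neighborhood similarity (LNS) on
  20-D nucleotide/dinucleotide frequency features;
* proteins — GIP kernel on adjacency columns, normalized pairwise alignment
  bit-score similarity, and LNS on composition/transition/distribution (CTD)
  physicochemical features.

All kernels are nonnegative with entries in [0, 1].  The GIP and expression
kernels are symmetric; the alignment and LNS kernels are generally not.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import squareform, pdist

from .datasets import (BitscoreMatrix, ExpressionProfiles, InteractionDataset,
                       SequenceSet)

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Three-group partitions of the 20 amino acids used by the CTD descriptors.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTCPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
}

# Ungapped Karlin-Altschul parameters for BLOSUM62, used to convert raw
# Smith-Waterman scores to bit scores: b = (lambda*S - ln K) / ln 2.
KARLIN_ALTSCHUL_LAMBDA = 0.3176
KARLIN_ALTSCHUL_K = 0.134


@dataclass
class SimilarityKernel:
    """A square nonnegative similarity matrix over one entity space."""

    values: np.ndarray
    ids: list[str]
    axis: str  # 'lncrna' | 'protein'
    source: str  # 'interaction' | 'expression' | 'alignment' | 'statfeat'
    scale_gamma: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.ids)
        if self.values.shape != (d, d):
            raise ValueError(f"kernel shape {self.values.shape} does not match {d} ids")
        if not np.isfinite(self.values).all():
            raise ValueError("kernel entries must be finite")
        if (self.values < 0).any():
            raise ValueError("kernel entries must be nonnegative")

    @property
    def dim(self) -> int:
        return len(self.ids)


@dataclass
class FeatureTable:
    """Entity id -> real feature vector, constant dimension across rows."""

    ids: list[str]
    values: np.ndarray
    axis: str
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("feature matrix shape does not match id list")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def gip_kernel(dataset: InteractionDataset, axis: str) -> SimilarityKernel:
    """Gaussian interaction-profile kernel on adjacency rows (lncRNA) or columns (protein).

    s(u, v) = exp(-gamma * ||A_u - A_v||^2) with the bandwidth gamma set to
    the entity count divided by the total squared profile norm, so the mean
    squared profile norm is mapped to unit scale.
    """
    if axis == "lncrna":
        profiles, ids = dataset.A, dataset.lncrna_ids
    elif axis == "protein":
        profiles, ids = dataset.A.T, dataset.protein_ids
    else:
        raise ValueError(f"unknown axis {axis!r}")
    total = float(np.sum(profiles ** 2))
    if total == 0.0:
        raise ValueError("GIP scale undefined (division by zero): adjacency is all-zero")
    gamma = profiles.shape[0] / total
    if profiles.shape[0] > 1:
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        d2 = np.zeros((1, 1))
    S = np.exp(-gamma * d2)
    return SimilarityKernel(S, list(ids), axis=axis, source="interaction", scale_gamma=gamma)


def expression_similarity(profiles: ExpressionProfiles) -> SimilarityKernel:
    """Pearson-correlation expression kernel: s(u,v) = (1 + rho)/2 off-diagonal, 0 on it.

    Zero-variance profiles (and any id flagged as imputed at load time) have
    undefined correlation; their similarities are set to 0 with a warning.
    """
    if profiles.dim < 2:
        raise ValueError("expression similarity needs >=2 profile dimensions")
    X = profiles.values
    sd = X.std(axis=1)
    degenerate = (sd == 0) | np.isin(profiles.ids, sorted(profiles.imputed_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(X)
    rho = np.nan_to_num(rho, nan=-1.0)  # (1+rho)/2 -> 0
    S = (1.0 + rho) / 2.0
    if degenerate.any():
        logger.warning("zero-variance/imputed expression profiles set to similarity 0: %s",
                       [profiles.ids[i] for i in np.flatnonzero(degenerate)])
        S[degenerate, :] = 0.0
        S[:, degenerate] = 0.0
    np.fill_diagonal(S, 0.0)
    S = np.clip(S, 0.0, 1.0)
    return SimilarityKernel(S, list(profiles.ids), axis="lncrna", source="expression")


def alignment_similarity(bitscores: BitscoreMatrix) -> SimilarityKernel:
    """Bit-score ratio kernel: s(u,v) = b(u,v)/b(u,u) off-diagonal, 0 on it.

    Not symmetrized — b(u,v)/b(u,u) != b(v,u)/b(v,v) in general.
    """
    b = bitscores.values
    diag = np.diag(b).copy()
    if (diag <= 0).any():
        bad = [bitscores.ids[i] for i in np.flatnonzero(diag <= 0)]
        raise ValueError(f"self bit score must be positive; offending proteins: {bad}")
    S = b / diag[:, None]
    if (S > 1.0 + 1e-12).any():
        logger.warning("bit scores exceeding self score clipped to ratio 1")
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 0.0)
    return SimilarityKernel(S, list(bitscores.ids), axis="protein", source="alignment")


def pairwise_bitscores(seqs: SequenceSet, matrix: str = "BLOSUM62",
                       gap_open: float = 11.0, gap_extend: float = 1.0,
                       ka_lambda: float = KARLIN_ALTSCHUL_LAMBDA,
                       ka_k: float = KARLIN_ALTSCHUL_K) -> BitscoreMatrix:
    """All-vs-all Smith-Waterman local alignment bit scores.

    Raw local-alignment scores under the given substitution matrix and affine
    gap penalties are converted to bits via the Karlin-Altschul formula
    b = (lambda * S_raw - ln K) / ln 2.  A deterministic, dependency-free
    stand-in for an external aligner; precomputed tabular scores can be
    supplied instead through :func:`lpiskf.datasets.read_bitscore_table`.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for sid, seq in seqs.sequences.items():
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    ids = seqs.ids
    n = len(ids)
    raw = np.zeros((n, n))
    for u in range(n):
        for v in range(u, n):
            s = float(aligner.score(seqs[ids[u]], seqs[ids[v]]))
            raw[u, v] = raw[v, u] = s
    bits = (ka_lambda * raw - math.log(ka_k)) / math.log(2.0)
    return BitscoreMatrix(list(ids), bits)


def lncrna_nucleotide_features(seqs: SequenceSet) -> FeatureTable:
    """20-D composition features: 4 nucleotide + 16 overlapping-dinucleotide frequencies.

    Each block is a frequency distribution summing to 1.
    """
    mono_index = {b: i for i, b in enumerate(RNA_BASES)}
    dinucs = ["".join(p) for p in product(RNA_BASES, repeat=2)]
    di_index = {d: i for i, d in enumerate(dinucs)}
    ids = seqs.ids
    X = np.zeros((len(ids), 20))
    for r, sid in enumerate(ids):
        seq = seqs[sid]
        if len(seq) < 2:
            raise ValueError(f"sequence {sid!r} too short for dinucleotide features")
        bad = set(seq) - set(RNA_BASES)
        if bad:
            raise ValueError(f"sequence {sid!r} has non-ACGU characters: {sorted(bad)}")
        for b in seq:
            X[r, mono_index[b]] += 1
        X[r, :4] /= len(seq)
        for i in range(len(seq) - 1):
            X[r, 4 + di_index[seq[i:i + 2]]] += 1
        X[r, 4:] /= len(seq) - 1
    names = list(RNA_BASES) + dinucs
    return FeatureTable(ids, X, axis="lncrna", feature_names=names)


def protein_ctd_features(seqs: SequenceSet,
                         properties: dict[str, tuple[str, str, str]] | None = None,
                         on_invalid: str = "skip") -> FeatureTable:
    """Composition/Transition/Distribution descriptors under 3-group partitions.

    Per property: 3 group-composition frequencies, 3 pairwise group-transition
    frequencies, and 5 distribution quantiles (first, 25%, 50%, 75%, 100%
    occurrence position / length) per group — 21 values, so the default four
    physicochemical properties give an 84-D vector.

    Residues outside the 20-letter alphabet are skipped with a warning by
    default (``on_invalid='error'`` raises).
    """
    if properties is None:
        properties = CTD_PROPERTIES
    for name, groups in properties.items():
        covered = "".join(groups)
        if sorted(covered) != sorted(AMINO_ACIDS):
            raise ValueError(f"property {name!r} does not partition the 20 amino acids")
    ids = seqs.ids
    dim = 21 * len(properties)
    X = np.zeros((len(ids), dim))
    names: list[str] = []
    for prop in properties:
        names += [f"{prop}.C{g}" for g in (1, 2, 3)]
        names += [f"{prop}.T{ab}" for ab in ("12", "13", "23")]
        names += [f"{prop}.D{g}q{q}" for g in (1, 2, 3) for q in (0, 25, 50, 75, 100)]
    for r, sid in enumerate(ids):
        seq = seqs[sid]
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            if on_invalid == "error":
                raise ValueError(f"sequence {sid!r} has invalid residues: {sorted(bad)}")
            logger.warning("sequence %s: skipping invalid residues %s", sid, sorted(bad))
            seq = "".join(c for c in seq if c in AMINO_ACIDS)
        if len(seq) < 2:
            raise ValueError(f"sequence {sid!r} too short for CTD features")
        offset = 0
        for prop, groups in properties.items():
            gmap = {}
            for g, letters in enumerate(groups):
                for c in letters:
                    gmap[c] = g
            labels = np.array([gmap[c] for c in seq])
            L = len(labels)
            # Composition
            for g in range(3):
                X[r, offset + g] = np.mean(labels == g)
            # Transition (unordered group pairs among adjacent residues)
            trans = list(zip(labels[:-1], labels[1:]))
            pairs = [(0, 1), (0, 2), (1, 2)]
            for t, (a, b) in enumerate(pairs):
                cnt = sum(1 for x, y in trans if {x, y} == {a, b})
                X[r, offset + 3 + t] = cnt / (L - 1)
            # Distribution: normalized positions of 1st/25/50/75/100% occurrence
            for g in range(3):
                pos = np.flatnonzero(labels == g) + 1  # 1-based
                base = offset + 6 + 5 * g
                if pos.size == 0:
                    continue
                for qi, frac in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
                    k = max(1, math.ceil(frac * pos.size))
                    X[r, base + qi] = pos[k - 1] / L
            offset += 21
    return FeatureTable(ids, X, axis="protein", feature_names=names)


def _lns_weights_nnls(x: np.ndarray, neighbors: np.ndarray, penalty: float = 1e6) -> np.ndarray:
    """Nonnegative simplex-constrained reconstruction weights via penalized NNLS.

    Solves min_w ||x - N^T w||^2 s.t. sum w = 1, w >= 0 by appending the
    sum-to-one constraint as a heavily weighted row; NNLS handles degenerate
    neighbor sets (duplicated points) natively.
    """
    k = neighbors.shape[0]
    scale = max(1.0, float(np.abs(x).max()))
    E = np.vstack([neighbors.T / scale, penalty * np.ones((1, k))])
    f = np.concatenate([x / scale, [penalty]])
    w, _ = nnls(E, f)
    total = w.sum()
    if total <= 0:
        return np.full(k, 1.0 / k)
    return w / total


def _lns_weights_equality(x: np.ndarray, neighbors: np.ndarray,
                          ridge: float = 1e-6) -> np.ndarray:
    """Equality-only reconstruction weights (signed), Gram solve with ridge fallback."""
    diff = x[None, :] - neighbors
    G = diff @ diff.T
    k = G.shape[0]
    tr = np.trace(G)
    if tr <= 0 or np.linalg.matrix_rank(G) < k:
        G = G + ridge * max(tr, 1.0) * np.eye(k)
    ones = np.ones(k)
    sol = np.linalg.solve(G, ones)
    return sol / (ones @ sol)


def lns_similarity(features: FeatureTable, k: int | None = None,
                   nonneg: bool = True) -> SimilarityKernel:
    """Linear neighborhood similarity from reconstruction weights.

    Each entity's feature vector is approximated as a convex combination of
    its k nearest neighbors (Euclidean distance, self excluded, ties broken by
    lower index); the optimal weights are the similarities: s(u, v) = w_v for
    v in N(u), 0 elsewhere.  Rows sum to 1, diagonal is 0, generally asymmetric.

    Default k: ceil(n/10) for lncRNAs, 3 for proteins.
    """
    n = len(features.ids)
    if k is None:
        k = max(1, math.ceil(n / 10)) if features.axis == "lncrna" else min(3, n - 1)
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < {n}")
    X = features.values
    d2 = squareform(pdist(X, metric="sqeuclidean")) if n > 1 else np.zeros((1, 1))
    S = np.zeros((n, n))
    for u in range(n):
        dist = d2[u].copy()
        dist[u] = np.inf
        order = np.lexsort((np.arange(n), dist))
        nbr = order[:k]
        if nonneg:
            w = _lns_weights_nnls(X[u], X[nbr])
        else:
            w = _lns_weights_equality(X[u], X[nbr])
        S[u, nbr] = w
    if nonneg:
        S = np.clip(S, 0.0, None)
    return SimilarityKernel(S, list(features.ids), axis=features.axis, source="statfeat")
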