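"""Input parsing and the bipartite interaction dataset.

Four artifact kinds are consumed: interaction pair lists (two-column text),
sequences (FASTA), lncRNA expression tables (TSV with a tissue header), and
protein-protein bit-score tables (BLAST tabular / outfmt 6).  All square and
rectangular matrices produced downstream are serialized as id-labelled TSV so
every intermediate can be inspected and round-tripped bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class InteractionDataset:
    """Ordered lncRNA/protein identifier lists plus the binary adjacency matrix.

    ``A[i, j] == 1`` iff lncRNA ``lncrna_ids[i]`` is known to interact with
    protein ``protein_ids[j]``.  Rows of A are lncRNA interaction profiles,
    columns are protein interaction profiles.
    """

    lncrna_ids: list[str]
    protein_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_ids = list(self.lncrna_ids)
        self.protein_ids = list(self.protein_ids)
        self.A = np.asarray(self.A, dtype=float)
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein identifiers")
        if self.A.ndim != 2 or self.A.shape != (len(self.lncrna_ids), len(self.protein_ids)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match id lists "
                f"({len(self.lncrna_ids)}, {len(self.protein_ids)})"
            )
        if self.n < 1 or self.m < 1:
            raise ValueError("dataset needs at least one lncRNA and one protein")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.lncrna_ids)

    @property
    def m(self) -> int:
        return len(self.protein_ids)

    def positives(self) -> list[tuple[int, int]]:
        """Indices (i, j) of all known interactions, row-major order."""
        return [tuple(ij) for ij in np.argwhere(self.A == 1)]

    def copy(self) -> "InteractionDataset":
        return InteractionDataset(list(self.lncrna_ids), list(self.protein_ids), self.A.copy())


@dataclass
class SequenceSet:
    """Identifier -> sequence map over a declared alphabet ('rna' or 'protein')."""

    sequences: dict[str, str]
    axis: str
    alphabet: str = "rna"
    invalid_chars: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        letters = RNA_ALPHABET if self.alphabet == "rna" else PROTEIN_ALPHABET
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")
            bad = set(seq) - letters
            if bad:
                self.invalid_chars[sid] = bad
                logger.warning("sequence %s contains non-%s characters: %s",
                               sid, self.alphabet, "".join(sorted(bad)))

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]


@dataclass
class ExpressionProfiles:
    """lncRNA expression vectors across a fixed panel of tissues."""

    ids: list[str]
    values: np.ndarray  # shape (n, t)
    tissues: list[str] | None = None
    imputed_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("expression matrix shape does not match id list")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def vector(self, sid: str) -> np.ndarray:
        return self.values[self.ids.index(sid)]


@dataclass
class BitscoreMatrix:
    """Pairwise protein bit scores b[u, v]; b[u, u] is the self-alignment score."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("bit-score matrix must be square over the id list")


def read_interaction_pairs(path, delimiter: str | None = None) -> tuple[list[tuple[str, str]], int]:
    """Parse a two-column interaction file into an ordered, de-duplicated pair list.

    Lines starting with '#' are comments.  Returns ``(pairs, n_duplicates)``;
    duplicates are counted and logged, first appearance wins.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns, got {len(fields)}")
            pair = (fields[0], fields[1])
            if pair in seen:
                n_dup += 1
            else:
                seen.add(pair)
                pairs.append(pair)
    if n_lines == 0:
        raise ValueError(f"{path}: no interaction pairs found")
    if n_dup:
        logger.info("%s: %d duplicate pair(s) dropped", path, n_dup)
    return pairs, n_dup


def build_adjacency(pairs, lncrna_ids=None, protein_ids=None) -> InteractionDataset:
    """Assemble the binary adjacency matrix from a pair list.

    When id lists are omitted they are frozen in first-appearance order from
    the pair list; all downstream matrices are indexed by these orders.
    """
    pairs = list(dict.fromkeys((str(a), str(b)) for a, b in pairs))
    if lncrna_ids is None:
        lncrna_ids = list(dict.fromkeys(a for a, _ in pairs))
    if protein_ids is None:
        protein_ids = list(dict.fromkeys(b for _, b in pairs))
    li = {s: i for i, s in enumerate(lncrna_ids)}
    pi = {s: j for j, s in enumerate(protein_ids)}
    unknown = [p for p in pairs if p[0] not in li or p[1] not in pi]
    if unknown:
        raise KeyError(f"pairs reference unknown identifiers: {unknown[:10]}")
    A = np.zeros((len(lncrna_ids), len(protein_ids)))
    for a, b in pairs:
        A[li[a], pi[b]] = 1.0
    return InteractionDataset(list(lncrna_ids), list(protein_ids), A)


def read_fasta(path, alphabet: str = "rna", axis: str | None = None,
               t_to_u: bool = True) -> SequenceSet:
    """Read a FASTA file; the header token before the first whitespace is the id.

    Sequences are upper-cased; for RNA, T is mapped to U by default (NONCODE
    FASTA files are DNA-alphabet).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sid = record.id
        if sid in sequences:
            raise ValueError(f"{path}: duplicate sequence id {sid!r}")
        seq = str(record.seq).upper()
        if alphabet == "rna" and t_to_u:
            seq = seq.replace("T", "U")
        if not seq:
            raise ValueError(f"{path}: record {sid!r} has no sequence")
        sequences[sid] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    if axis is None:
        axis = "lncrna" if alphabet == "rna" else "protein"
    return SequenceSet(sequences, axis=axis, alphabet=alphabet)


def read_expression_table(path, missing: str = "error") -> ExpressionProfiles:
    """Read a TSV expression table: header of tissue names, first column = lncRNA id.

    ``missing='error'`` rejects rows with non-numeric cells (row number named);
    ``missing='zero'`` imputes an all-zero profile with a warning and flags the
    id so the expression kernel can assign it zero similarity.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expected a header row of tissue names and >=1 column")
    tissues = [str(c) for c in df.columns]
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate lncRNA ids")
    values = np.zeros((len(ids), len(tissues)))
    imputed: set = set()
    for r, (sid, row) in enumerate(df.iterrows(), start=1):
        numeric = pd.to_numeric(row, errors="coerce")
        if numeric.isna().any():
            if missing == "zero":
                logger.warning("%s: row %d (%s) has missing values; imputing zeros", path, r, sid)
                values[r - 1] = 0.0
                imputed.add(str(sid))
            else:
                raise ValueError(f"{path}: row {r} ({sid}) has non-numeric cells")
        else:
            values[r - 1] = numeric.to_numpy(dtype=float)
    return ExpressionProfiles(ids, values, tissues=tissues, imputed_ids=imputed)


def read_bitscore_table(path, protein_ids=None) -> BitscoreMatrix:
    """Read BLAST tabular (outfmt 6) output into a bit-score matrix.

    b[u, v] is the best (maximum) bit score over all HSP lines for (u, v);
    pairs with no line get 0.  Column 12 must hold the bit score.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 columns (outfmt 6), got {len(fields)}")
            q, s = fields[0], fields[1]
            try:
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad bit score {fields[11]!r}") from exc
            key = (q, s)
            if key not in best or bits > best[key]:
                best[key] = bits
            for sid in (q, s):
                if sid not in seen:
                    seen.add(sid)
                    order.append(sid)
    if protein_ids is None:
        protein_ids = order
    idx = {s: i for i, s in enumerate(protein_ids)}
    values = np.zeros((len(protein_ids), len(protein_ids)))
    for (q, s), bits in best.items():
        if q in idx and s in idx:
            values[idx[q], idx[s]] = bits
    return BitscoreMatrix(list(protein_ids), values)


def write_matrix_tsv(path, values, row_ids, col_ids) -> None:
    """Write an id-labelled matrix as TSV (full float repr, bit-exact round-trip)."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
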