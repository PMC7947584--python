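"""Alignment column statistics: position-based sequence weights, consensus
scoring against a substitution matrix, column homogeneity, and trimming.

The homogeneity H of an alignment column scales the weighted consensus score
Q_c between the random expectation Q_R (weighted score against an amino acid
drawn from the background frequencies) and the maximum attainable score
S(c,c), clamped at zero:

    Q_x = sum_i w_i S(a_i, x)        (weights renormalized over non-gap rows)
    c   = argmax_x Q_x
    Q_R = sum_b f_b Q_b
    H   = max((Q_c - Q_R) / (S(c,c) - Q_R), 0)

H is 1 exactly when every (non-gap) row carries the same residue and 0 when
the column scores no better than random.  Sequence weights w_i are the
position-based weights of Henikoff & Henikoff: in each column, a residue
type shared by s of the rows among r distinct types present contributes
1/(r*s) to each of those rows; row weights are the per-column sums,
normalized to sum to 1 over the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, GAP, Msa, SubstitutionMatrix


@dataclass(frozen=True)
class WeightVector:
    """Per-row sequence weights in alignment row order, summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("negative sequence weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum():.12f}, not 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ColumnStats:
    """Summary statistics of one alignment column (0-based index)."""

    column_index: int
    gap_fraction: float
    consensus: str | None
    q_consensus: float
    q_random: float
    homogeneity: float


def henikoff_weights(msa: Msa) -> WeightVector:
    """Position-based sequence weights for the rows of ``msa``.

    Gaps (and ambiguity codes) are not residue types: a column's 1/(r*s)
    masses are distributed only among rows carrying a standard residue.
    Raises if a row has no scorable residue at all.
    """
    idx = msa.to_indices()
    n, L = idx.shape
    if np.any((idx >= 0).sum(axis=1) == 0):
        bad = msa.ids[int(np.argmin((idx >= 0).sum(axis=1)))]
        raise ValueError(f"row {bad!r} has no scorable residues (all gaps)")
    raw = np.zeros(n)
    for j in range(L):
        col = idx[:, j]
        present = col >= 0
        if not present.any():
            continue
        counts = np.bincount(col[present], minlength=20)
        r = int((counts > 0).sum())
        # each row with residue a gets 1 / (r * count_a)
        contrib = np.zeros(n)
        contrib[present] = 1.0 / (r * counts[col[present]])
        raw += contrib
    total = raw.sum()
    if total <= 0:
        raise ValueError("alignment has no scorable residues")
    return WeightVector(raw / total)


def _column_q_vector(
    idx_col: np.ndarray, weights: np.ndarray, matrix: SubstitutionMatrix
) -> np.ndarray:
    """Q_x for all 20 amino acids x, with weights renormalized over the
    non-gap rows of the column.  Raises on an all-gap column."""
    present = idx_col >= 0
    if not present.any():
        raise ValueError("all-gap column has no column score")
    w = weights[present]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("column weight mass is zero")
    w = w / wsum
    return w @ matrix.scores[idx_col[present], :]


def column_score(
    msa: Msa,
    weights: WeightVector,
    column_index: int,
    x: str,
    matrix: SubstitutionMatrix,
) -> float:
    """Weighted score Q_x of a column against amino acid ``x``."""
    q = _column_q_vector(msa.to_indices()[:, column_index], weights.weights, matrix)
    return float(q[AMINO_ACIDS.index(x)])


def consensus_residue(
    msa: Msa,
    weights: WeightVector,
    column_index: int,
    matrix: SubstitutionMatrix,
) -> str | None:
    """The consensus amino acid c = argmax_x Q_x, or None for an all-gap
    column.  Ties break alphabetically."""
    idx_col = msa.to_indices()[:, column_index]
    if not (idx_col >= 0).any():
        return None
    q = _column_q_vector(idx_col, weights.weights, matrix)
    return AMINO_ACIDS[_argmax_alphabetical(q)]


def random_expectation_score(
    msa: Msa,
    weights: WeightVector,
    column_index: int,
    matrix: SubstitutionMatrix,
) -> float:
    """Q_R = sum_b f_b Q_b over the 20 amino acids."""
    q = _column_q_vector(msa.to_indices()[:, column_index], weights.weights, matrix)
    return float(matrix.background @ q)


def _argmax_alphabetical(q: np.ndarray, tol: float = 1e-9) -> int:
    """First (alphabetical) index whose Q is within ``tol`` of the maximum.

    Exact Q ties are real (e.g. a column where two residues score equally
    against the whole column); summation order must not decide them.
    """
    return int(np.flatnonzero(q >= q.max() - tol)[0])


def _homogeneity_from_q(q: np.ndarray, matrix: SubstitutionMatrix) -> tuple[str, float, float, float]:
    c_idx = _argmax_alphabetical(q)
    qc = float(q[c_idx])
    qr = float(matrix.background @ q)
    scc = float(matrix.scores[c_idx, c_idx])
    denom = scc - qr
    if abs(denom) < 1e-12:
        if abs(qc - scc) < 1e-9:
            return AMINO_ACIDS[c_idx], qc, qr, 1.0
        raise ValueError(
            "degenerate column: S(c,c) equals the random expectation score"
        )
    h = max((qc - qr) / denom, 0.0)
    return AMINO_ACIDS[c_idx], qc, qr, min(h, 1.0)


def column_homogeneity(
    msa: Msa,
    weights: WeightVector,
    column_index: int,
    matrix: SubstitutionMatrix,
) -> float:
    """Homogeneity H of one column, in [0, 1]."""
    q = _column_q_vector(msa.to_indices()[:, column_index], weights.weights, matrix)
    return _homogeneity_from_q(q, matrix)[3]


def column_stats(
    msa: Msa, matrix: SubstitutionMatrix, weights: WeightVector | None = None
) -> list[ColumnStats]:
    """Per-column gap fraction, consensus and homogeneity for a whole MSA.

    All-gap columns get consensus None, gap_fraction 1 and homogeneity 0
    (they carry no signal and are always trimmed by the gap rule).
    """
    if weights is None:
        weights = henikoff_weights(msa)
    idx = msa.to_indices()
    n, L = idx.shape
    out: list[ColumnStats] = []
    for j in range(L):
        col = idx[:, j]
        gaps = int((col < 0).sum())
        gap_fraction = gaps / n
        if gaps == n:
            out.append(ColumnStats(j, 1.0, None, float("nan"), float("nan"), 0.0))
            continue
        q = _column_q_vector(col, weights.weights, matrix)
        c, qc, qr, h = _homogeneity_from_q(q, matrix)
        out.append(ColumnStats(j, gap_fraction, c, qc, qr, h))
    return out


def trim_alignment(
    msa: Msa,
    max_gap_fraction: float = 0.50,
    min_homogeneity: float = 0.10,
    matrix: SubstitutionMatrix | None = None,
    joint: bool = False,
) -> tuple[Msa, list[int]]:
    """Remove low-signal alignment columns.

    By default a column is removed when it has MORE than ``max_gap_fraction``
    gaps OR LESS than ``min_homogeneity`` homogeneity, i.e. a column is kept
    only when it passes both thresholds (boundary values pass).  With
    ``joint=True`` removal requires both violations simultaneously.
    Returns the trimmed alignment and the strictly increasing list of kept
    column indices.
    """
    from .io import load_builtin_matrix

    if matrix is None:
        matrix = load_builtin_matrix("BLOSUM62")
    stats = column_stats(msa, matrix)
    kept: list[int] = []
    for st in stats:
        gap_bad = st.gap_fraction > max_gap_fraction
        hom_bad = st.homogeneity < min_homogeneity
        removed = (gap_bad and hom_bad) if joint else (gap_bad or hom_bad)
        if not removed:
            kept.append(st.column_index)
    if not kept:
        raise ValueError(
            "trimming removed every column; relax max_gap_fraction or "
            "min_homogeneity"
        )
    rows = tuple(
        (rid, "".join(seq[j] for j in kept)) for rid, seq in msa.records
    )
    return Msa(rows), kept


def column_to_reference_position(
    msa: Msa, reference_row_id: str, column_index: int
) -> int | None:
    """Map an alignment column to the 1-based ungapped position in a
    reference row; None when the reference is gapped at that column."""
    seq = msa.row(reference_row_id)
    if seq[column_index] == GAP:
        return None
    return len(seq[: column_index + 1].replace(GAP, ""))
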