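"""Readers and writers for the external formats the pipeline touches.

All on-disk formats are plain text: FASTA for ungapped protein sequences,
aligned FASTA (gap character ``-``) for multiple sequence alignments, GFF3
for gene features, and tab-separated tables for profile hits, cluster
assignments and prophage regions.  Coordinates in GFF3 are 1-based inclusive
on disk and are preserved unchanged through a read/write round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 standard amino acids in alphabetical one-letter order. This order
#: fixes the row/column order of substitution matrices and all argmax
#: tie-breaks throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Letters accepted on input but treated as gaps by scoring and weighting
#: operations (ambiguity codes and selenocysteine have no background
#: frequency entry).
AMBIGUOUS_LETTERS = frozenset("XBZUJO*")

GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        if GAP in self.residues or "." in self.residues:
            raise FormatError(
                f"sequence {self.id!r} contains gap characters; "
                "use read_alignment for aligned input"
            )
        bad = set(self.residues.upper()) - set(AMINO_ACIDS) - AMBIGUOUS_LETTERS
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-amino-acid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length gapped rows.

    ``records`` is an ordered tuple of ``(id, gapped_sequence)`` pairs.
    Degapping any row yields a valid :class:`SequenceRecord`.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment with no rows")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{rid}:{len(s)}" for rid, s in self.records[:5]
            )
            raise FormatError(f"ragged alignment rows (lengths {detail} ...)")
        (length,) = lengths
        if length == 0:
            raise FormatError("alignment with zero columns")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate row id {dup!r} in alignment")
        for rid, seq in self.records:
            degapped = seq.replace(GAP, "").replace(".", "")
            if degapped:
                SequenceRecord(rid, degapped)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, row_id: str) -> str:
        for rid, seq in self.records:
            if rid == row_id:
                return seq
        raise KeyError(f"no alignment row with id {row_id!r}")

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.records)

    def degap(self) -> list[SequenceRecord]:
        """Recover the ungapped sequences, preserving row order."""
        return [
            SequenceRecord(rid, seq.replace(GAP, ""))
            for rid, seq in self.records
        ]

    def to_indices(self) -> np.ndarray:
        """Encode as an (N, L) int8 array; standard residues map to their
        index in :data:`AMINO_ACIDS`, gaps and ambiguity codes to -1."""
        arr = np.full((self.n_rows, self.n_cols), -1, dtype=np.int8)
        for i, (_, seq) in enumerate(self.records):
            for j, ch in enumerate(seq.upper()):
                arr[i, j] = AA_INDEX.get(ch, -1)
        return arr


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid substitution matrix with background
    frequencies.

    ``scores[i, j]`` scores the pair ``AMINO_ACIDS[i], AMINO_ACIDS[j]``;
    ``background`` holds relative frequencies f_b summing to 1.
    """

    name: str
    scores: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        f = np.asarray(self.background, dtype=float)
        if s.shape != (20, 20):
            raise ValueError(f"{self.name}: scores must be 20x20, got {s.shape}")
        if not np.allclose(s, s.T):
            raise ValueError(f"{self.name}: substitution matrix not symmetric")
        if f.shape != (20,):
            raise ValueError(f"{self.name}: background must have 20 entries")
        if np.any(f <= 0):
            raise ValueError(f"{self.name}: background frequencies must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: background frequencies sum to {f.sum():.12f}, not 1"
            )
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "background", f)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[AA_INDEX[a], AA_INDEX[b]])


@dataclass(frozen=True)
class ProfileHit:
    """A profile-vs-sequence match record (one row of a hit table)."""

    sequence_id: str
    sequence_length: int
    profile_id: str
    profile_length: int
    profile_kind: str  # full | n_terminal | c_terminal
    profile_span: tuple[int, int]  # inclusive, 1-based profile columns
    sequence_span: tuple[int, int]  # inclusive, 1-based residues
    evalue: float

    _KINDS = ("full", "n_terminal", "c_terminal")

    def __post_init__(self) -> None:
        if self.profile_kind not in self._KINDS:
            raise FormatError(
                f"hit {self.sequence_id}/{self.profile_id}: profile_kind "
                f"{self.profile_kind!r} not one of {self._KINDS}"
            )
        for (lo, hi), length, what in (
            (self.profile_span, self.profile_length, "profile"),
            (self.sequence_span, self.sequence_length, "sequence"),
        ):
            if not (1 <= lo <= hi <= length):
                raise FormatError(
                    f"hit {self.sequence_id}/{self.profile_id}: {what}_span "
                    f"{lo}-{hi} outside 1-{length}"
                )
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.sequence_id}/{self.profile_id}: negative evalue"
            )

    @property
    def profile_coverage(self) -> float:
        lo, hi = self.profile_span
        return (hi - lo + 1) / self.profile_length


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a replicon (GFF3 convention: 1-based inclusive)."""

    replicon_id: str
    start: int
    end: int
    strand: str
    family: str
    label: str = "unlabeled"
    feature_id: str = ""

    def __post_init__(self) -> None:
        if not self.replicon_id:
            raise FormatError("gene feature with empty replicon id")
        if self.start > self.end:
            raise FormatError(
                f"feature {self.feature_id or self.family} on {self.replicon_id}: "
                f"start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(
                f"feature on {self.replicon_id}: start {self.start} < 1"
            )
        if self.label not in ("rcgta_like", "virus_like", "unlabeled"):
            raise FormatError(f"unknown feature label {self.label!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`."""
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq)))
    if not rows:
        raise FormatError(f"no alignment rows in {path}")
    return Msa(tuple(rows))


def write_alignment(msa: Msa, path) -> None:
    bio = [_BioSeqRecord(Seq(seq), id=rid, description="") for rid, seq in msa.records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "sequence_id",
    "sequence_length",
    "profile_id",
    "profile_length",
    "profile_kind",
    "profile_start",
    "profile_end",
    "sequence_start",
    "sequence_end",
    "evalue",
]


def read_hits(path) -> list[ProfileHit]:
    """Read a tab-separated profile-hit table (documented header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"hit table {path} missing columns {missing}")
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hits.append(
                ProfileHit(
                    sequence_id=row.sequence_id,
                    sequence_length=int(row.sequence_length),
                    profile_id=row.profile_id,
                    profile_length=int(row.profile_length),
                    profile_kind=row.profile_kind,
                    profile_span=(int(row.profile_start), int(row.profile_end)),
                    sequence_span=(int(row.sequence_start), int(row.sequence_end)),
                    evalue=float(row.evalue),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    return hits


def write_hits(hits, path) -> None:
    rows = [
        {
            "sequence_id": h.sequence_id,
            "sequence_length": h.sequence_length,
            "profile_id": h.profile_id,
            "profile_length": h.profile_length,
            "profile_kind": h.profile_kind,
            "profile_start": h.profile_span[0],
            "profile_end": h.profile_span[1],
            "sequence_start": h.sequence_span[0],
            "sequence_end": h.sequence_span[1],
            "evalue": h.evalue,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 features
# ---------------------------------------------------------------------------

def read_features(path) -> list[GeneFeature]:
    """Read gene features from GFF3.

    The homolog family is carried in a ``family=`` attribute and the
    GTA-Hunter-style classification in a ``label=`` attribute; features
    without a label are ``unlabeled``.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            family = (f.attributes.get("family") or ["other"])[0]
            label = (f.attributes.get("label") or ["unlabeled"])[0]
            fid = (f.attributes.get("ID") or [""])[0]
            try:
                features.append(
                    GeneFeature(
                        replicon_id=f.seqid,
                        start=f.start,
                        end=f.end,
                        strand=f.strand if f.strand in "+-" else "+",
                        family=family,
                        label=label,
                        feature_id=fid,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return features


def write_features(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.feature_id:
                attrs.append(f"ID={f.feature_id}")
            attrs.append(f"family={f.family}")
            if f.label != "unlabeled":
                attrs.append(f"label={f.label}")
            fh.write(
                f"{f.replicon_id}\tterlkit\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# substitution matrices
# ---------------------------------------------------------------------------

# BLOSUM62 marginal background frequencies (standard published values,
# alphabetical amino-acid order; they sum to exactly 1.000).
_BLOSUM62_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

_MATRIX_CACHE: dict[str, SubstitutionMatrix] = {}
_AVAILABLE_MATRICES = ("BLOSUM62",)


def load_builtin_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a shipped substitution matrix with its background frequencies."""
    key = name.upper()
    if key not in _AVAILABLE_MATRICES:
        raise ValueError(
            f"unknown matrix {name!r}; available: {', '.join(_AVAILABLE_MATRICES)}"
        )
    if key not in _MATRIX_CACHE:
        from Bio.Align import substitution_matrices

        raw = substitution_matrices.load(key)
        scores = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                scores[i, j] = raw[a, b]
        background = np.array([_BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
        _MATRIX_CACHE[key] = SubstitutionMatrix(key, scores, background)
    return _MATRIX_CACHE[key]
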