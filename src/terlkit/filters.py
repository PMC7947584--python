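"""Curation filters that remove partial TerL sequences before and after
alignment.

A complete large terminase carries two domains: an N-terminal ATPase and a
C-terminal nuclease.  ``domain_coverage_filter`` keeps a sequence only when
its profile hits demonstrate both domains — either through one hit covering
most of a full-length (two-domain) profile, or through separate matches on
the N- and C-terminal sides, each leaving enough unmatched sequence to house
the other domain.  After alignment, ``consensus_similarity_filter`` and
``pssm_coverage_filter`` remove rows that score poorly against the alignment
consensus or cover too little of it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .alnstats import column_stats, henikoff_weights
from .io import GAP, Msa, ProfileHit, SequenceRecord, SubstitutionMatrix


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of one filter rule for one sequence."""

    sequence_id: str
    kept: bool
    rule: str
    detail: str

    _RULES = (
        "full_profile_75",
        "two_profile_domains",
        "domain_plus_margin",
        "consensus_score",
        "pssm_coverage",
        "walker_a_rescue",
    )

    def __post_init__(self) -> None:
        if self.rule not in self._RULES:
            raise ValueError(f"unknown filter rule {self.rule!r}")
        if not self.kept and not self.detail:
            raise ValueError("removal decision must state the failed threshold")


# ---------------------------------------------------------------------------
# domain coverage (pre-alignment)
# ---------------------------------------------------------------------------

def _domain_side_matches(
    hit: ProfileHit, sequence_length: int, domain_cov: float, margin: float
) -> str | None:
    """Return 'N' or 'C' when the hit counts as a match over that terminal
    domain, else None.

    A domain-specific profile match must cover >= domain_cov of its profile;
    a partial full-profile hit counts for the side its matched columns lie on
    (classified by the midpoint of the profile span).  In both cases at least
    ``margin`` of the sequence length must lie outside the matched sequence
    span on the side where the unmatched domain would be: C-ward of an
    N-side match, N-ward of a C-side match.
    """
    seq_lo, seq_hi = hit.sequence_span
    room_nward = seq_lo - 1
    room_cward = sequence_length - seq_hi

    if hit.profile_kind in ("n_terminal", "c_terminal"):
        if hit.profile_coverage < domain_cov:
            return None
        side = "N" if hit.profile_kind == "n_terminal" else "C"
    else:  # partial hit to a full two-domain profile
        if hit.profile_coverage >= domain_cov:
            # covers most of both domains; handled by the full-profile clause
            return None
        lo, hi = hit.profile_span
        midpoint = (lo + hi) / 2
        side = "N" if midpoint <= hit.profile_length / 2 else "C"

    room = room_cward if side == "N" else room_nward
    if room >= margin * sequence_length:
        return side
    return None


def domain_coverage_filter(
    sequence_length: int,
    hits: list[ProfileHit],
    full_cov: float = 0.75,
    domain_cov: float = 0.75,
    margin: float = 0.35,
) -> FilterDecision:
    """Decide whether a sequence demonstrably carries both TerL domains."""
    if not hits:
        return FilterDecision("?", False, "full_profile_75", "no hits")
    sid = hits[0].sequence_id
    if any(h.sequence_id != sid for h in hits):
        raise ValueError("hits belong to different sequences")

    # clause (a): one hit covering >= full_cov of a full two-domain profile
    for h in hits:
        if h.profile_kind == "full" and h.profile_coverage >= full_cov:
            return FilterDecision(
                sid,
                True,
                "full_profile_75",
                f"hit to {h.profile_id} covers "
                f"{h.profile_coverage:.0%} of full profile (>= {full_cov:.0%})",
            )

    # clause (b): separate matches over the N- and C-terminal domains
    n_match = c_match = None
    for h in hits:
        side = _domain_side_matches(h, sequence_length, domain_cov, margin)
        if side == "N" and n_match is None:
            n_match = h
        elif side == "C" and c_match is None:
            c_match = h
    if n_match is not None and c_match is not None and n_match is not c_match:
        return FilterDecision(
            sid,
            True,
            "two_profile_domains",
            f"N-side match {n_match.profile_id} "
            f"({n_match.sequence_span[0]}-{n_match.sequence_span[1]}) and "
            f"C-side match {c_match.profile_id} "
            f"({c_match.sequence_span[0]}-{c_match.sequence_span[1]})",
        )

    missing = "C" if n_match is not None else ("N" if c_match is not None else "both")
    return FilterDecision(
        sid,
        False,
        "two_profile_domains" if (n_match or c_match) else "full_profile_75",
        f"no full-profile hit >= {full_cov:.0%} and no domain pair "
        f"(missing {missing}-side match with >= {margin:.0%} of "
        f"{sequence_length} aa left for the other domain)",
    )


# ---------------------------------------------------------------------------
# post-alignment filters
# ---------------------------------------------------------------------------

def consensus_similarity_filter(
    msa: Msa,
    matrix: SubstitutionMatrix,
    min_fraction: float = 0.10,
) -> list[FilterDecision]:
    """Remove rows scoring below ``min_fraction`` of the perfect-match score
    against the alignment consensus.

    The perfect-match score is the score of a hypothetical row identical to
    the consensus at every consensus-defined column; a row contributes
    S(a_i, c) at each such column where it carries a residue.
    """
    # rows without any residue cannot enter the weight computation; they are
    # scored (as zero) against the consensus of the remaining rows
    occupied = tuple(
        (rid, seq) for rid, seq in msa.records if seq.replace(GAP, "")
    )
    if not occupied:
        raise ValueError("every row is all-gap; no consensus defined")
    core = Msa(occupied) if len(occupied) < msa.n_rows else msa
    weights = henikoff_weights(core)
    stats = column_stats(core, matrix, weights)
    cons_cols = [(st.column_index, st.consensus) for st in stats if st.consensus]
    if not cons_cols:
        raise ValueError("consensus undefined on every column")
    perfect = sum(matrix.score(c, c) for _, c in cons_cols)
    decisions = []
    idx = msa.to_indices()
    from .io import AMINO_ACIDS

    for i, rid in enumerate(msa.ids):
        score = 0.0
        for j, c in cons_cols:
            a = idx[i, j]
            if a >= 0:
                score += matrix.score(AMINO_ACIDS[a], c)
        kept = score >= min_fraction * perfect
        decisions.append(
            FilterDecision(
                rid,
                kept,
                "consensus_score",
                f"score {score:.1f} vs perfect {perfect:.1f} "
                f"(ratio {score / perfect:.3f}, threshold {min_fraction})",
            )
        )
    return decisions


def pssm_coverage_filter(
    msa: Msa, min_cov: float = 0.75
) -> tuple[list[FilterDecision], dict[str, SequenceRecord]]:
    """Keep rows covering >= ``min_cov`` of the consensus-defined columns;
    extract each kept row's residues between its first and last non-gap
    consensus-defined column."""
    from .io import load_builtin_matrix

    matrix = load_builtin_matrix("BLOSUM62")
    occupied = tuple(
        (rid, seq) for rid, seq in msa.records if seq.replace(GAP, "")
    )
    if not occupied:
        raise ValueError("every row is all-gap; no consensus defined")
    core = Msa(occupied) if len(occupied) < msa.n_rows else msa
    stats = column_stats(core, matrix)
    cons_cols = [st.column_index for st in stats if st.consensus]
    if not cons_cols:
        raise ValueError("consensus undefined on every column")
    decisions: list[FilterDecision] = []
    extracted: dict[str, SequenceRecord] = {}
    for rid, seq in msa.records:
        covered = [j for j in cons_cols if seq[j] != GAP]
        coverage = len(covered) / len(cons_cols)
        kept = coverage >= min_cov
        decisions.append(
            FilterDecision(
                rid,
                kept,
                "pssm_coverage",
                f"residues at {len(covered)}/{len(cons_cols)} consensus "
                f"columns (coverage {coverage:.3f}, threshold {min_cov})",
            )
        )
        if kept:
            lo, hi = covered[0], covered[-1]
            residues = seq[lo : hi + 1].replace(GAP, "")
            extracted[rid] = SequenceRecord(rid, residues)
    return decisions, extracted


WALKER_A = re.compile(r"[AG].{4}GK[ST]")


def detect_walker_a(sequence: str | SequenceRecord) -> int | None:
    """1-based start of the first Walker A (P-loop) motif [AG]x(4)GK[S/T],
    or None."""
    residues = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    m = WALKER_A.search(residues.upper())
    return m.start() + 1 if m else None


def walker_a_rescue(
    record: SequenceRecord,
    hits: list[ProfileHit],
    min_length: int = 300,
    max_evalue: float = 1e-3,
) -> FilterDecision:
    """Rescue decision for sequences failing to align: keep when the
    sequence is long enough, has a significant profile hit, and carries a
    Walker A motif."""
    long_enough = len(record) >= min_length
    best_e = min((h.evalue for h in hits), default=float("inf"))
    significant = best_e < max_evalue
    motif = detect_walker_a(record)
    kept = long_enough and significant and motif is not None
    return FilterDecision(
        record.id,
        kept,
        "walker_a_rescue",
        f"length {len(record)} (>= {min_length}: {long_enough}), "
        f"best evalue {best_e:g} (< {max_evalue:g}: {significant}), "
        f"Walker A at {motif}",
    )


def select_representatives(
    clusters: dict[str, list[SequenceRecord]]
) -> dict[str, SequenceRecord]:
    """Pick the median-length member of each cluster.

    Even-sized clusters take the shorter of the two middle lengths; ties on
    length break by lexicographic id.
    """
    out: dict[str, SequenceRecord] = {}
    for cid, members in clusters.items():
        if not members:
            raise ValueError(f"cluster {cid!r} is empty")
        ordered = sorted(members, key=lambda r: (len(r), r.id))
        out[cid] = ordered[(len(ordered) - 1) // 2]
    return out
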