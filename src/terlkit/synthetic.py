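"""Seeded generators for every input class the pipeline consumes, with
planted ground truth for parameter-recovery tests.

Each generator is a pure function of its arguments (the seed is mandatory),
so identical calls produce byte-identical outputs.  The simulations are
deliberately minimal: per-site i.i.d. substitution from the BLOSUM62
background frequencies, no indels except whole-domain truncations, no rate
heterogeneity.  They exercise the curation, clustering and classification
machinery, not phylogenetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    GAP,
    GeneFeature,
    Msa,
    ProfileHit,
    SequenceRecord,
    load_builtin_matrix,
)
from .sites import GROUP1, GROUP3, GroupedMsa

#: A canonical Walker A (P-loop) motif instance: matches [AG]x(4)GK[ST].
WALKER_A_SEQ = "GPSGSGKS"


def _rng(seed: int) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)):
        raise ValueError("seed must be an integer")
    return np.random.default_rng(int(seed))


def _draw_residues(rng: np.random.Generator, n: int, background: np.ndarray) -> str:
    idx = rng.choice(20, size=n, p=background)
    return "".join(AMINO_ACIDS[i] for i in idx)


# ---------------------------------------------------------------------------
# random MSAs with controlled conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaTruth:
    conserved_columns: tuple[int, ...]


def simulate_msa(
    n_rows: int,
    n_cols: int,
    conservation_p: float,
    gap_p: float,
    seed: int,
) -> tuple[Msa, MsaTruth]:
    """Random alignment with a controlled fraction of conserved columns.

    Each column is, with probability ``conservation_p``, fully conserved
    (one residue drawn from the background frequencies, shared by all rows);
    otherwise every row draws independently.  Gaps are then inserted per
    cell with probability ``gap_p`` (rows that would end up all-gap get one
    residue restored so every row stays scorable).
    """
    if not (0 <= conservation_p <= 1 and 0 <= gap_p <= 1):
        raise ValueError("conservation_p and gap_p must lie in [0, 1]")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be positive")
    rng = _rng(seed)
    background = load_builtin_matrix("BLOSUM62").background
    grid = np.empty((n_rows, n_cols), dtype="<U1")
    conserved = []
    for j in range(n_cols):
        if rng.random() < conservation_p:
            res = AMINO_ACIDS[rng.choice(20, p=background)]
            grid[:, j] = res
            conserved.append(j)
        else:
            grid[:, j] = list(_draw_residues(rng, n_rows, background))
    if gap_p > 0:
        gaps = rng.random((n_rows, n_cols)) < gap_p
        for i in range(n_rows):
            if gaps[i].all():
                gaps[i, rng.integers(n_cols)] = False
            grid[i, gaps[i]] = GAP
    rows = tuple((f"s{i + 1}", "".join(grid[i])) for i in range(n_rows))
    return Msa(rows), MsaTruth(tuple(conserved))


# ---------------------------------------------------------------------------
# two-group MSAs with planted discriminative sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """Specification of one planted discriminative column.

    ``purity1``/``purity3`` give the within-group relative abundance of the
    planted residue.  ``cross1`` (``cross3``) optionally puts the OTHER
    group's planted residue into that fraction of group 1 (group 3) rows —
    emulating, e.g., a site where 99% of one group and 4% of the other carry
    the same cysteine.  The remainder of each group carries a fixed
    alternative residue.  All fractions are realized as exact row counts
    (rounded to the nearest integer) so boundary behavior of the scanner is
    deterministic.
    """

    column: int
    residue_g1: str
    residue_g3: str
    purity1: float
    purity3: float
    cross1: float = 0.0
    cross3: float = 0.0


@dataclass(frozen=True)
class TwoGroupTruth:
    planted_columns: tuple[int, ...]


def simulate_two_group_msa(
    n1: int,
    n3: int,
    n_cols: int,
    planted_sites: list[PlantedSite],
    seed: int,
) -> tuple[GroupedMsa, TwoGroupTruth]:
    """Two-group alignment, identical across groups except at planted sites.

    Non-planted columns are fully conserved (one background residue shared
    by every row of both groups).  At a planted column, round(purity * n)
    rows of each group carry the planted residue and the rest carry a fixed
    alternative; which rows carry which is shuffled by the seed.
    """
    rng = _rng(seed)
    background = load_builtin_matrix("BLOSUM62").background
    planted = {p.column: p for p in planted_sites}
    for p in planted_sites:
        if not (0 <= p.column < n_cols):
            raise ValueError(f"planted column {p.column} outside 0..{n_cols - 1}")
        if not (0 <= p.purity1 <= 1 and 0 <= p.purity3 <= 1):
            raise ValueError("purities must lie in [0, 1]")
        if p.residue_g1 == p.residue_g3 and p.purity1 == p.purity3 == 1:
            raise ValueError(
                f"planted column {p.column} is non-discriminative "
                "(same residue fixed in both groups)"
            )
    n = n1 + n3
    grid = np.empty((n, n_cols), dtype="<U1")
    for j in range(n_cols):
        if j in planted:
            p = planted[j]
            for (offset, size, res, purity, other_res, cross) in (
                (0, n1, p.residue_g1, p.purity1, p.residue_g3, p.cross1),
                (n1, n3, p.residue_g3, p.purity3, p.residue_g1, p.cross3),
            ):
                k = int(round(purity * size))
                kx = int(round(cross * size)) if other_res != res else 0
                if k + kx > size:
                    raise ValueError(
                        f"planted column {j}: purity + cross exceed 1"
                    )
                alt = _alternative_residue({res, other_res}, rng)
                col = [res] * k + [other_res] * kx + [alt] * (size - k - kx)
                rng.shuffle(col)
                grid[offset : offset + size, j] = col
        else:
            grid[:, j] = AMINO_ACIDS[rng.choice(20, p=background)]
    ids = [f"g1_{i + 1}" for i in range(n1)] + [f"g3_{i + 1}" for i in range(n3)]
    rows = tuple((rid, "".join(grid[i])) for i, rid in enumerate(ids))
    group_of = {rid: (GROUP1 if rid.startswith("g1_") else GROUP3) for rid in ids}
    return GroupedMsa(Msa(rows), group_of), TwoGroupTruth(tuple(sorted(planted)))


def _alternative_residue(excluded: set[str], rng: np.random.Generator) -> str:
    choices = [a for a in AMINO_ACIDS if a not in excluded]
    return choices[rng.integers(len(choices))]


# ---------------------------------------------------------------------------
# TerL-like protein families with planted truncations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTruth:
    truncated_ids: tuple[str, ...]
    motif_offset: int  # 1-based Walker A start in the root (and full seqs)
    kept_domain: dict[str, str] = field(default_factory=dict)  # id -> N or C


def simulate_terl_family(
    n_full: int,
    n_truncated: int,
    length: int,
    divergence: float,
    seed: int,
    family_name: str = "fam",
) -> tuple[list[SequenceRecord], list[ProfileHit], FamilyTruth]:
    """A two-domain TerL-like protein family with truncation artifacts.

    A root sequence of ``length`` residues carries a Walker A motif in its
    N-terminal half.  Full-length descendants substitute each non-motif site
    with probability ``divergence`` (replacement drawn from the background).
    Truncated descendants keep a single domain: the N-terminal 55% or the
    C-terminal 55% of the protein.  The accompanying hit table gives full
    sequences a near-complete hit to a full two-domain profile, and
    truncated sequences a single domain-profile hit, so the domain-coverage
    filter can be scored against the planted truth.
    """
    if length < 300:
        raise ValueError("length must be at least 300")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must lie in [0, 1)")
    rng = _rng(seed)
    background = load_builtin_matrix("BLOSUM62").background
    motif_offset = max(1, length // 6)  # 1-based, inside the N-terminal half
    root = list(_draw_residues(rng, length, background))
    root[motif_offset - 1 : motif_offset - 1 + len(WALKER_A_SEQ)] = WALKER_A_SEQ
    motif_sites = set(range(motif_offset - 1, motif_offset - 1 + len(WALKER_A_SEQ)))

    def _descend() -> str:
        child = list(root)
        for k in range(length):
            if k in motif_sites:
                continue
            if rng.random() < divergence:
                child[k] = AMINO_ACIDS[rng.choice(20, p=background)]
        return "".join(child)

    full_profile = f"{family_name}_full"
    n_profile = f"{family_name}_nterm"
    c_profile = f"{family_name}_cterm"
    half = int(round(length * 0.55))
    records: list[SequenceRecord] = []
    hits: list[ProfileHit] = []
    truncated_ids: list[str] = []
    kept_domain: dict[str, str] = {}
    for i in range(n_full):
        sid = f"{family_name}_full_{i + 1}"
        seq = _descend()
        records.append(SequenceRecord(sid, seq))
        hits.append(
            ProfileHit(
                sequence_id=sid,
                sequence_length=length,
                profile_id=full_profile,
                profile_length=length,
                profile_kind="full",
                profile_span=(1 + length // 20, length - length // 20),
                sequence_span=(1 + length // 20, length - length // 20),
                evalue=1e-30,
            )
        )
    for i in range(n_truncated):
        sid = f"{family_name}_trunc_{i + 1}"
        seq = _descend()
        side = "N" if rng.random() < 0.5 else "C"
        kept = seq[:half] if side == "N" else seq[-half:]
        records.append(SequenceRecord(sid, kept))
        truncated_ids.append(sid)
        kept_domain[sid] = side
        dom_len = int(round(length * 0.45))
        hits.append(
            ProfileHit(
                sequence_id=sid,
                sequence_length=len(kept),
                profile_id=n_profile if side == "N" else c_profile,
                profile_length=dom_len,
                profile_kind="n_terminal" if side == "N" else "c_terminal",
                profile_span=(1, dom_len),
                # the single-domain hit spans nearly the whole truncated
                # sequence, leaving no room for the missing domain
                sequence_span=(1, len(kept) - 5),
                evalue=1e-20,
            )
        )
    truth = FamilyTruth(tuple(truncated_ids), motif_offset, kept_domain)
    return records, hits, truth


@dataclass(frozen=True)
class RelatedFamiliesTruth:
    family_of: dict[str, str]


def simulate_related_families(
    n_families: int,
    n_per_family: int,
    length: int,
    within_divergence: float,
    between_divergence: float,
    seed: int,
) -> tuple[list[SequenceRecord], RelatedFamiliesTruth]:
    """Several subfamilies descending from one common root sequence.

    Each subfamily root diverges from the common root at
    ``between_divergence`` per site; members diverge from their subfamily
    root at ``within_divergence``.  With within << 0.5 and between moderate,
    identity clustering at 0.5 recovers the subfamilies and the subfamily
    profiles stay similar enough to merge, which is the regime the
    iterative aligner is meant to handle.
    """
    if not (0 <= within_divergence < 1 and 0 <= between_divergence < 1):
        raise ValueError("divergences must lie in [0, 1)")
    rng = _rng(seed)
    background = load_builtin_matrix("BLOSUM62").background
    root = _draw_residues(rng, length, background)

    def _mutate(seq: str, rate: float) -> str:
        out = list(seq)
        for k in range(len(out)):
            if rng.random() < rate:
                out[k] = AMINO_ACIDS[rng.choice(20, p=background)]
        return "".join(out)

    records: list[SequenceRecord] = []
    family_of: dict[str, str] = {}
    for f in range(n_families):
        fam_root = _mutate(root, between_divergence)
        fam_name = f"fam{f + 1}"
        for i in range(n_per_family):
            sid = f"{fam_name}_m{i + 1}"
            records.append(SequenceRecord(sid, _mutate(fam_root, within_divergence)))
            family_of[sid] = fam_name
    return records, RelatedFamiliesTruth(family_of)


# ---------------------------------------------------------------------------
# replicon gene neighborhoods with planted elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cassette:
    """A planted run of RcGTA-like genes around a terL gene."""

    replicon: str
    start: int
    n_distinct_families: int
    intergene_gap: int = 500
    label: str = "rcgta_like"
    prophage: str | None = None  # None | intact | questionable


@dataclass(frozen=True)
class NeighborhoodTruth:
    expected_calls: dict[str, str]  # terL feature id -> expected call
    cassette_spans: dict[str, tuple[int, int]]


def simulate_neighborhood(
    cassettes: list[Cassette],
    n_background: int = 5,
    seed: int = 0,
    gene_length: int = 1000,
) -> tuple[list[GeneFeature], pd.DataFrame, NeighborhoodTruth]:
    """Replicon gene maps with planted RcGTA-like cassettes.

    Each cassette places a terL gene followed by ``n_distinct_families``
    distinct marker-family genes at ``intergene_gap`` spacing (the gap must
    stay below the 8 kb chaining cutoff).  Background genes of family
    ``other`` are scattered at least 20 kb from every cassette.  The ground
    truth records the element call the classifier is expected to make for
    each planted terL, including the effect of any planted prophage.
    """
    from .elements import DEFAULT_COUNTED_FAMILIES

    rng = _rng(seed)
    if any(c.intergene_gap >= 8000 for c in cassettes):
        raise ValueError("cassette intergene gaps must be below 8000 bp")
    features: list[GeneFeature] = []
    prophage_rows: list[dict] = []
    expected: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for ci, cas in enumerate(cassettes, start=1):
        if cas.n_distinct_families > len(DEFAULT_COUNTED_FAMILIES):
            raise ValueError(
                f"cassette asks for {cas.n_distinct_families} families; only "
                f"{len(DEFAULT_COUNTED_FAMILIES)} are defined"
            )
        terl_id = f"terL_{ci}"
        pos = cas.start
        end_terl = pos + gene_length - 1
        features.append(
            GeneFeature(cas.replicon, pos, end_terl, "+", "terL", "rcgta_like", terl_id)
        )
        pos = end_terl + cas.intergene_gap + 1
        last_end = end_terl
        for fam in DEFAULT_COUNTED_FAMILIES[: cas.n_distinct_families]:
            end = pos + gene_length - 1
            features.append(
                GeneFeature(
                    cas.replicon, pos, end, "+", fam, cas.label, f"{fam}_{ci}"
                )
            )
            last_end = end
            pos = end + cas.intergene_gap + 1
        span = (cas.start, last_end)
        spans[terl_id] = span
        for lo, hi in occupied.get(cas.replicon, []):
            if not (span[1] < lo or span[0] > hi):
                raise ValueError(
                    f"cassette {ci} on {cas.replicon} overlaps another cassette"
                )
        occupied.setdefault(cas.replicon, []).append(span)
        n_counted = cas.n_distinct_families if cas.label == "rcgta_like" else 0
        if n_counted >= 6:
            call = "large_element"
        elif n_counted >= 1:
            call = "small_element"
        else:
            call = "none"
        # a planted prophage overrides exactly as the classifier would:
        # intact supersedes small/none, questionable only none, large never
        if cas.prophage == "intact" and call != "large_element":
            call = "prophage_intact"
        elif cas.prophage == "questionable" and call == "none":
            call = "prophage_questionable"
        expected[terl_id] = call
        if cas.prophage is not None:
            prophage_rows.append(
                {
                    "replicon": cas.replicon,
                    "start": max(1, span[0] - 1000),
                    "end": span[1] + 1000,
                    "status": cas.prophage,
                }
            )
    # background genes at least 20 kb away from every cassette
    replicons = sorted({c.replicon for c in cassettes}) or ["rep1"]
    for bi in range(n_background):
        rep = replicons[int(rng.integers(len(replicons)))]
        for _ in range(200):
            start = int(rng.integers(1, 2_000_000))
            end = start + gene_length - 1
            if all(
                end < lo - 20_000 or start > hi + 20_000
                for lo, hi in occupied.get(rep, [])
            ):
                features.append(
                    GeneFeature(rep, start, end, "+", "other", "unlabeled", f"bg_{bi + 1}")
                )
                occupied.setdefault(rep, []).append((start, end))
                break
    prophages = pd.DataFrame(
        prophage_rows, columns=["replicon", "start", "end", "status"]
    )
    return features, prophages, NeighborhoodTruth(expected, spans)
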