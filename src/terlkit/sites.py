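"""Scan a two-group alignment for group-discriminative conserved sites.

A column is a candidate when the modal amino acid of group 1 (virus-like)
or group 3 (RcGTA-like) exceeds 80% relative abundance within that group
(gaps excluded from the denominator).  A candidate is retained when the
between-group difference in the relative abundance of that conserved
residue is at least 70%.  Retained sites are reported in the 1-based
ungapped coordinates of a chosen reference row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .alnstats import column_to_reference_position
from .io import AMINO_ACIDS, GAP, Msa

GROUP1 = "group1"
GROUP3 = "group3"


@dataclass(frozen=True)
class GroupedMsa:
    """An alignment whose rows carry group labels (group1/group3/other)."""

    msa: Msa
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.group_of) - set(self.msa.ids)
        if unknown:
            raise ValueError(f"group labels for unknown rows {sorted(unknown)}")
        for g in (GROUP1, GROUP3):
            if not any(v == g for v in self.group_of.values()):
                raise ValueError(f"group {g} is empty")

    def rows_in(self, group: str) -> list[str]:
        return [rid for rid in self.msa.ids if self.group_of.get(rid) == group]


@dataclass(frozen=True)
class SiteCall:
    """One retained discriminative column."""

    column_index: int
    group1_modal: str | None
    group1_abundance: float
    group3_modal: str | None
    group3_abundance: float
    difference: float
    direction: str  # group1 | group3 | both


def group_column_profile(
    grouped: GroupedMsa, column_index: int, group: str
) -> tuple[str | None, float]:
    """Modal residue of a group at a column and its relative abundance among
    the group's non-gap rows.  Ties break alphabetically; an all-gap group
    column yields (None, 0)."""
    rows = grouped.rows_in(group)
    if not rows:
        raise ValueError(f"unknown or empty group {group!r}")
    residues = [
        grouped.msa.row(rid)[column_index].upper()
        for rid in rows
    ]
    residues = [r for r in residues if r in AMINO_ACIDS]
    if not residues:
        return None, 0.0
    counts = Counter(residues)
    top = max(counts.values())
    modal = min(a for a, c in counts.items() if c == top)
    return modal, top / len(residues)


def _abundance_of(grouped: GroupedMsa, column_index: int, group: str, residue: str) -> float:
    rows = grouped.rows_in(group)
    residues = [
        grouped.msa.row(rid)[column_index].upper() for rid in rows
    ]
    residues = [r for r in residues if r in AMINO_ACIDS]
    if not residues:
        return 0.0
    return residues.count(residue) / len(residues)


def scan_discriminative_sites(
    grouped: GroupedMsa,
    conservation_min: float = 0.80,
    difference_min: float = 0.70,
    max_group_gap_fraction: float = 0.50,
) -> list[SiteCall]:
    """Find columns conserved (> ``conservation_min``, strict) in group 1 or
    group 3 with between-group abundance difference >= ``difference_min``
    (inclusive) for the conserved residue.

    Columns where either group is more than ``max_group_gap_fraction``
    gapped are skipped: sparse columns would otherwise look conserved on a
    handful of residues.
    """
    msa = grouped.msa
    g1_rows, g3_rows = grouped.rows_in(GROUP1), grouped.rows_in(GROUP3)
    calls: list[SiteCall] = []
    for j in range(msa.n_cols):
        skip = False
        for rows in (g1_rows, g3_rows):
            col = [msa.row(rid)[j] for rid in rows]
            if col.count(GAP) / len(col) > max_group_gap_fraction:
                skip = True
                break
        if skip:
            continue
        m1, a1 = group_column_profile(grouped, j, GROUP1)
        m3, a3 = group_column_profile(grouped, j, GROUP3)
        directions = []
        if a1 > conservation_min and m1 is not None:
            diff1 = abs(a1 - _abundance_of(grouped, j, GROUP3, m1))
            if diff1 >= difference_min:
                directions.append((GROUP1, diff1))
        if a3 > conservation_min and m3 is not None:
            diff3 = abs(a3 - _abundance_of(grouped, j, GROUP1, m3))
            if diff3 >= difference_min:
                directions.append((GROUP3, diff3))
        if not directions:
            continue
        direction = "both" if len(directions) == 2 else directions[0][0]
        difference = max(d for _, d in directions)
        calls.append(SiteCall(j, m1, a1, m3, a3, difference, direction))
    return calls


def report_sites(
    calls: list[SiteCall], grouped: GroupedMsa, reference_row_id: str
) -> pd.DataFrame:
    """Annotate site calls with 1-based ungapped reference positions."""
    if reference_row_id not in grouped.msa.ids:
        raise KeyError(f"no alignment row with id {reference_row_id!r}")
    rows = []
    for c in calls:
        pos = column_to_reference_position(grouped.msa, reference_row_id, c.column_index)
        rows.append(
            {
                "column": c.column_index,
                "ref_position": "none" if pos is None else pos,
                "group1_modal": c.group1_modal or "none",
                "group1_abund": round(c.group1_abundance, 6),
                "group3_modal": c.group3_modal or "none",
                "group3_abund": round(c.group3_abundance, 6),
                "difference": round(c.difference, 6),
                "direction": c.direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "column",
            "ref_position",
            "group1_modal",
            "group1_abund",
            "group3_modal",
            "group3_abund",
            "difference",
            "direction",
        ],
    )
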