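"""Genomic-neighborhood analysis: chain RcGTA-homolog genes into regions and
classify each terL-containing region.

Gene features on one replicon are chained into regions by single-linkage
clustering in one dimension: adjacent genes whose boundary gap is at most
8,000 bp (the default) belong to one region.  A region containing a terL
gene is then called a large RcGTA-like element when at least 6 of the 11
RcGTA head-tail marker families are present (distinct families, excluding
terL itself, counting only genes classified rcgta_like), a small element
with 1-5 such families, and nothing otherwise.  Externally predicted
prophages can supersede small-element and no-element calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io import GeneFeature

#: The 11 RcGTA head-tail cluster marker families counted toward element
#: size (terL, the g2 gene, is deliberately absent).  Configurable in
#: :func:`classify_terl_regions`.
DEFAULT_COUNTED_FAMILIES = (
    "g3", "g4", "g5", "g6", "g7", "g8", "g9", "g12", "g13", "g14", "g15",
)

TERL_FAMILIES = ("terL", "terl", "g2")


@dataclass(frozen=True)
class Region:
    """A chained run of gene features on one replicon."""

    replicon_id: str
    members: tuple[GeneFeature, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(f.start for f in self.members),
            max(f.end for f in self.members),
        )


@dataclass(frozen=True)
class ElementCall:
    """Classification of one terL-containing region."""

    terl: GeneFeature
    region: Region
    n_distinct_families: int
    families: tuple[str, ...]
    call: str  # large_element | small_element | none | prophage_intact | prophage_questionable


def _is_terl(f: GeneFeature) -> bool:
    return f.family in TERL_FAMILIES


def chain_regions(
    features: list[GeneFeature], max_gap: int = 8000
) -> list[Region]:
    """Single-linkage chaining of features along each replicon.

    Two adjacent features join one region when the gap between them (start
    of the downstream feature minus end of the upstream one, floored at 0
    for overlaps) is at most ``max_gap``.  Strand is ignored; features never
    chain across replicons.
    """
    if any(not f.replicon_id for f in features):
        raise ValueError("feature with empty replicon id")
    by_rep: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_rep.setdefault(f.replicon_id, []).append(f)
    regions: list[Region] = []
    for rep in sorted(by_rep):
        feats = sorted(by_rep[rep], key=lambda f: (f.start, f.end, f.family))
        current = [feats[0]]
        max_end = feats[0].end
        for f in feats[1:]:
            gap = max(0, f.start - max_end)
            if gap <= max_gap:
                current.append(f)
            else:
                regions.append(Region(rep, tuple(current)))
                current = [f]
            max_end = max(max_end, f.end)
        regions.append(Region(rep, tuple(current)))
    return regions


def classify_terl_regions(
    regions: list[Region],
    counted_families: tuple[str, ...] = DEFAULT_COUNTED_FAMILIES,
) -> list[ElementCall]:
    """Call each terL-containing region by its distinct rcgta_like marker
    family count: >= 6 large, 1-5 small, 0 none."""
    calls: list[ElementCall] = []
    for region in regions:
        for f in region.members:
            if not _is_terl(f):
                continue
            fams = sorted(
                {
                    g.family
                    for g in region.members
                    if not _is_terl(g)
                    and g.label == "rcgta_like"
                    and g.family in counted_families
                }
            )
            n = len(fams)
            if n >= 6:
                call = "large_element"
            elif n >= 1:
                call = "small_element"
            else:
                call = "none"
            calls.append(ElementCall(f, region, n, tuple(fams), call))
    return calls


def read_prophage_table(path) -> pd.DataFrame:
    """Read a TSV of externally predicted prophage regions
    (replicon, start, end, status in {intact, questionable})."""
    df = pd.read_csv(path, sep="\t", dtype={"replicon": str, "status": str})
    required = {"replicon", "start", "end", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prophage table {path} missing columns {sorted(missing)}")
    bad = set(df["status"]) - {"intact", "questionable"}
    if bad:
        raise ValueError(f"prophage table {path}: unknown status values {sorted(bad)}")
    if (df["start"].astype(int) > df["end"].astype(int)).any():
        raise ValueError(f"prophage table {path}: start > end")
    return df


def apply_prophage_override(
    calls: list[ElementCall], prophage_regions: pd.DataFrame
) -> list[ElementCall]:
    """Let prophage predictions supersede weak element calls.

    An intact prophage overlapping a region (by at least 1 bp) relabels a
    small_element or none call as prophage_intact; a questionable prophage
    relabels only none calls.  Large elements are never overridden.
    """
    if prophage_regions.empty:
        return list(calls)
    out: list[ElementCall] = []
    for call in calls:
        lo, hi = call.region.span
        new_call = call.call
        for row in prophage_regions.itertuples(index=False):
            if row.replicon != call.region.replicon_id:
                continue
            if int(row.end) < lo or int(row.start) > hi:
                continue
            if row.status == "intact" and call.call in ("small_element", "none"):
                new_call = "prophage_intact"
                break
            if row.status == "questionable" and call.call == "none":
                new_call = "prophage_questionable"
        out.append(replace(call, call=new_call) if new_call != call.call else call)
    return out


def calls_to_frame(calls: list[ElementCall]) -> pd.DataFrame:
    """Flatten element calls into the output table."""
    rows = [
        {
            "replicon": c.region.replicon_id,
            "terL_id": c.terl.feature_id or f"{c.region.replicon_id}:{c.terl.start}",
            "region_start": c.region.span[0],
            "region_end": c.region.span[1],
            "n_distinct_families": c.n_distinct_families,
            "family_list": ",".join(c.families),
            "call": c.call,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "replicon",
            "terL_id",
            "region_start",
            "region_end",
            "n_distinct_families",
            "family_list",
            "call",
        ],
    )
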