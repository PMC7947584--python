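"""Propagation of experimentally determined DNA-packaging strategies across
sequence-similarity clusters.

Closely related terminases are assumed to share their packaging mechanism:
an unlabeled member of a cluster that contains an experimentally
characterized virus inherits that virus's strategy.  Clusters whose
experimental members disagree are flagged ambiguous and excluded rather
than resolved by vote — within-cluster homogeneity is the assumption being
leaned on, so violations must surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

STRATEGIES = ("headful", "cos", "dtr", "host_ends")


@dataclass(frozen=True)
class PackagingLabel:
    """A packaging-strategy assignment for one sequence."""

    sequence_id: str
    strategy: str
    evidence: str  # experimental | propagated
    source: str = ""  # the experimentally labeled cluster-mate, if propagated

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown packaging strategy {self.strategy!r}")
        if self.evidence not in ("experimental", "propagated"):
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.evidence == "propagated" and not self.source:
            raise ValueError("propagated label must name its source sequence")


def propagate_packaging(
    assignments: dict[str, str],
    experimental_labels: dict[str, str],
) -> list[PackagingLabel]:
    """Spread experimental labels to unlabeled cluster-mates.

    Returns one row per labeled sequence: experimental labels echoed as-is,
    plus propagated labels naming their source.  Clusters containing
    conflicting experimental labels produce no rows and emit a warning.
    """
    missing = set(experimental_labels) - set(assignments)
    if missing:
        raise ValueError(
            f"experimentally labeled ids missing from cluster assignments: "
            f"{sorted(missing)}"
        )
    members: dict[str, list[str]] = {}
    for sid in sorted(assignments):
        members.setdefault(assignments[sid], []).append(sid)
    out: list[PackagingLabel] = []
    for cid in sorted(members):
        labeled = [
            (sid, experimental_labels[sid])
            for sid in members[cid]
            if sid in experimental_labels
        ]
        if not labeled:
            continue
        strategies = {s for _, s in labeled}
        if len(strategies) > 1:
            warnings.warn(
                f"cluster {cid!r} has conflicting experimental labels "
                f"{sorted(strategies)}; members excluded from propagation",
                stacklevel=2,
            )
            continue
        strategy = strategies.pop()
        source = labeled[0][0]
        for sid in members[cid]:
            if sid in experimental_labels:
                out.append(PackagingLabel(sid, experimental_labels[sid], "experimental"))
            else:
                out.append(PackagingLabel(sid, strategy, "propagated", source))
    return out


def labels_to_frame(labels: list[PackagingLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": l.sequence_id,
                "strategy": l.strategy,
                "evidence": l.evidence,
                "source": l.source,
            }
            for l in labels
        ],
        columns=["id", "strategy", "evidence", "source"],
    )


def read_cluster_table(path) -> dict[str, str]:
    """TSV of (id, cluster_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "cluster_id"} <= set(df.columns):
        raise ValueError(f"cluster table {path} needs columns id, cluster_id")
    return dict(zip(df["id"], df["cluster_id"]))


def read_label_table(path) -> dict[str, str]:
    """TSV of (id, strategy)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "strategy"} <= set(df.columns):
        raise ValueError(f"label table {path} needs columns id, strategy")
    return dict(zip(df["id"], df["strategy"]))
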