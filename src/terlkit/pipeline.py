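"""Config-driven orchestration of the curation pipeline.

Stages run in order — domain filtering, iterative alignment, consensus and
coverage filtering, trimming, element classification, site scanning, label
propagation — with each enabled stage writing its artifact plus a log line
of input/output counts.  Phylogenetic tree inference is deliberately an
external hook: the pipeline's terminal sequence artifact is the trimmed
alignment, which FastTree/IQ-TREE or any other inference tool consumes.

Every stage is deterministic given the inputs and configuration, so a rerun
with the stored config reproduces each artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import alnstats, elements, filters, iteralign, labels as labels_mod, sites as sites_mod
from .io import (
    Msa,
    load_builtin_matrix,
    read_alignment,
    read_fasta,
    read_features,
    read_hits,
    write_alignment,
    write_fasta,
)


@dataclass
class PipelineConfig:
    """All pipeline knobs, defaulting to the study's working values."""

    # inputs (any may be None to skip the stages that need it)
    sequences: str | None = None
    hits: str | None = None
    features: str | None = None
    prophages: str | None = None
    groups: str | None = None
    clusters: str | None = None
    packaging_labels: str | None = None
    reference_row: str | None = None

    # stage toggles
    run_domain_filter: bool = True
    run_iteralign: bool = True
    run_consensus_filter: bool = True
    run_coverage_filter: bool = True
    run_trim: bool = True
    run_elements: bool = True
    run_sites: bool = True
    run_labels: bool = True

    # thresholds (defaults are the published working values)
    full_profile_cov: float = 0.75
    domain_cov: float = 0.75
    domain_margin: float = 0.35
    cluster_threshold: float = 0.5
    depth_threshold: float = 2.3
    max_iterations: int = 20
    mask_max_gap: float = 0.67
    consensus_min_fraction: float = 0.10
    pssm_min_cov: float = 0.75
    trim_max_gap: float = 0.50
    trim_min_homogeneity: float = 0.10
    element_max_gap: int = 8000
    site_conservation_min: float = 0.80
    site_difference_min: float = 0.70

    out_dir: str = "pipeline_out"


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    log_rows: list[dict] = []

    def _log(stage: str, n_in: int, n_out: int, removed_ids: list[str]) -> None:
        log_rows.append(
            {
                "stage": stage,
                "in": n_in,
                "out": n_out,
                "removed": n_in - n_out,
                "removed_ids": ",".join(sorted(removed_ids)),
            }
        )

    matrix = load_builtin_matrix("BLOSUM62")
    records = None
    if config.sequences:
        records = read_fasta(config.sequences)

    if config.run_domain_filter:
        if records is None or not config.hits:
            if records is not None and not config.hits:
                raise PipelineError("domain_filter stage enabled but no hit table given")
        else:
            hits = read_hits(config.hits)
            by_seq: dict[str, list] = {}
            for h in hits:
                by_seq.setdefault(h.sequence_id, []).append(h)
            kept, decisions = [], []
            for rec in records:
                decision = filters.domain_coverage_filter(
                    len(rec),
                    by_seq.get(rec.id, []),
                    config.full_profile_cov,
                    config.domain_cov,
                    config.domain_margin,
                )
                decisions.append(decision)
                if decision.kept:
                    kept.append(rec)
            _write_decisions(decisions, out / "domain_filter_decisions.tsv")
            write_fasta(kept, out / "domain_filtered.fasta")
            _log(
                "domain_filter",
                len(records),
                len(kept),
                [d.sequence_id for d in decisions if not d.kept],
            )
            records = kept

    alignment: Msa | None = None
    if config.run_iteralign:
        if records is None:
            raise PipelineError("iteralign stage enabled but no sequences available")
        cfg = iteralign.IterAlignConfig(
            cluster_threshold=config.cluster_threshold,
            depth_threshold=config.depth_threshold,
            max_iterations=config.max_iterations,
            max_gap_mask=config.mask_max_gap,
        )
        result = iteralign.iterate_align(records, cfg)
        alignment = result.alignment
        write_alignment(alignment, out / "aligned.fasta")
        pd.DataFrame(
            {"iteration": range(len(result.block_counts)), "blocks": result.block_counts}
        ).to_csv(out / "iteralign_log.tsv", sep="\t", index=False)
        _log("iteralign", len(records), alignment.n_rows, result.unaligned_ids)

    if config.run_consensus_filter and alignment is not None:
        decisions = filters.consensus_similarity_filter(
            alignment, matrix, config.consensus_min_fraction
        )
        kept_ids = {d.sequence_id for d in decisions if d.kept}
        _write_decisions(decisions, out / "consensus_filter_decisions.tsv")
        n_in = alignment.n_rows
        alignment = Msa(
            tuple((rid, seq) for rid, seq in alignment.records if rid in kept_ids)
        )
        _log(
            "consensus_filter",
            n_in,
            alignment.n_rows,
            [d.sequence_id for d in decisions if not d.kept],
        )

    if config.run_coverage_filter and alignment is not None:
        decisions, _extracted = filters.pssm_coverage_filter(
            alignment, config.pssm_min_cov
        )
        kept_ids = {d.sequence_id for d in decisions if d.kept}
        _write_decisions(decisions, out / "coverage_filter_decisions.tsv")
        n_in = alignment.n_rows
        alignment = Msa(
            tuple((rid, seq) for rid, seq in alignment.records if rid in kept_ids)
        )
        _log(
            "coverage_filter",
            n_in,
            alignment.n_rows,
            [d.sequence_id for d in decisions if not d.kept],
        )

    if config.run_trim and alignment is not None:
        trimmed, kept_cols = alnstats.trim_alignment(
            alignment, config.trim_max_gap, config.trim_min_homogeneity, matrix
        )
        write_alignment(trimmed, out / "trimmed.fasta")
        pd.DataFrame({"kept_column": kept_cols}).to_csv(
            out / "kept_columns.tsv", sep="\t", index=False
        )
        log_rows.append(
            {
                "stage": "trim",
                "in": alignment.n_cols,
                "out": trimmed.n_cols,
                "removed": alignment.n_cols - trimmed.n_cols,
                "removed_ids": "",
            }
        )
        alignment = trimmed

    if config.run_elements and config.features:
        feats = read_features(config.features)
        regions = elements.chain_regions(feats, config.element_max_gap)
        calls = elements.classify_terl_regions(regions)
        if config.prophages:
            prophage_df = elements.read_prophage_table(config.prophages)
            calls = elements.apply_prophage_override(calls, prophage_df)
        elements.calls_to_frame(calls).to_csv(
            out / "element_calls.tsv", sep="\t", index=False
        )
        _log("elements", len(feats), len(calls), [])

    if config.run_sites and config.groups and alignment is not None:
        group_df = pd.read_csv(config.groups, sep="\t", dtype=str)
        present = set(alignment.ids)
        group_of = {
            rid: grp
            for rid, grp in zip(group_df["id"], group_df["group"])
            if rid in present
        }
        grouped = sites_mod.GroupedMsa(alignment, group_of)
        calls = sites_mod.scan_discriminative_sites(
            grouped, config.site_conservation_min, config.site_difference_min
        )
        ref = config.reference_row or alignment.ids[0]
        sites_mod.report_sites(calls, grouped, ref).to_csv(
            out / "site_calls.tsv", sep="\t", index=False
        )
        _log("sites", alignment.n_cols, len(calls), [])

    if config.run_labels and config.clusters and config.packaging_labels:
        assignments = labels_mod.read_cluster_table(config.clusters)
        exp = labels_mod.read_label_table(config.packaging_labels)
        assigned = labels_mod.propagate_packaging(assignments, exp)
        labels_mod.labels_to_frame(assigned).to_csv(
            out / "packaging_labels.tsv", sep="\t", index=False
        )
        _log("labels", len(assignments), len(assigned), [])

    pd.DataFrame(
        log_rows, columns=["stage", "in", "out", "removed", "removed_ids"]
    ).to_csv(out / "log.tsv", sep="\t", index=False)
    return out


def _write_decisions(decisions, path) -> None:
    pd.DataFrame(
        [
            {
                "sequence_id": d.sequence_id,
                "kept": d.kept,
                "rule": d.rule,
                "detail": d.detail,
            }
            for d in decisions
        ],
        columns=["sequence_id", "kept", "rule", "detail"],
    ).to_csv(path, sep="\t", index=False)
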