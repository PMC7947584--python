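"""End-to-end pipeline run on simulated inputs.

Generates a TerL-like family with truncations plus a gene neighborhood,
writes all input files, runs every pipeline stage, and prints the stage log.
Rerunning with the same inputs reproduces every artifact byte for byte.
"""

import tempfile
from pathlib import Path

import pandas as pd

from terlkit.io import write_fasta, write_features, write_hits
from terlkit.pipeline import PipelineConfig, run_pipeline
from terlkit.synthetic import Cassette, simulate_neighborhood, simulate_terl_family

workdir = Path(tempfile.mkdtemp(prefix="terlkit_example_"))

records, hits, _ = simulate_terl_family(12, 4, 320, divergence=0.15, seed=71)
features, prophages, _ = simulate_neighborhood(
    [Cassette("rep1", 10_000, 7), Cassette("rep2", 5_000, 2, prophage="intact")],
    n_background=4,
    seed=72,
)

write_fasta(records, workdir / "seqs.fasta")
write_hits(hits, workdir / "hits.tsv")
write_features(features, workdir / "features.gff")
prophages.to_csv(workdir / "prophages.tsv", sep="\t", index=False)

full_ids = [r.id for r in records if "full" in r.id]
pd.DataFrame(
    {"id": full_ids, "group": ["group1" if i % 2 == 0 else "group3" for i in range(len(full_ids))]}
).to_csv(workdir / "groups.tsv", sep="\t", index=False)
pd.DataFrame({"id": [r.id for r in records], "cluster_id": "c1"}).to_csv(
    workdir / "clusters.tsv", sep="\t", index=False
)
pd.DataFrame({"id": [records[0].id], "strategy": ["headful"]}).to_csv(
    workdir / "labels.tsv", sep="\t", index=False
)

config = PipelineConfig(
    sequences=str(workdir / "seqs.fasta"),
    hits=str(workdir / "hits.tsv"),
    features=str(workdir / "features.gff"),
    prophages=str(workdir / "prophages.tsv"),
    groups=str(workdir / "groups.tsv"),
    clusters=str(workdir / "clusters.tsv"),
    packaging_labels=str(workdir / "labels.tsv"),
    out_dir=str(workdir / "run"),
)
out = run_pipeline(config)

print(f"artifacts in {out}:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
print("\nstage log:")
print(pd.read_csv(out / "log.tsv", sep="\t").to_string(index=False))
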