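# terlkit

Tools for curating large-terminase (TerL) protein datasets and for finding
gene-transfer-agent-like (GTA-like) elements in bacterial genomes.

TerL is the two-domain (ATPase + nuclease) motor that packages DNA into
viral and GTA capsids. Building a trustworthy TerL phylogeny from homology
searches requires solving several recurring curation problems, and terlkit
implements them as a library:

- **Column statistics** — Henikoff position-based sequence weights,
  per-column consensus and homogeneity scores, and alignment trimming.
- **Partial-sequence filters** — profile-coverage rules that remove
  single-domain truncations, a consensus-similarity filter, a PSSM-coverage
  filter, and Walker A motif ([AG]x₄GK[S/T]) rescue.
- **Iterative alignment** — greedy identity clustering, profile–profile
  progressive alignment along a UPGMA guide tree, and iterative merging of
  alignment blocks until convergence.
- **Element classification** — chaining of genes near *terL* into regions
  (gap ≤ 8 kb) and classification into large (≥ 6 distinct RcGTA-like marker
  families), small (1–5), or none, with prophage-call overrides.
- **Discriminative sites** — columns conserved within each of two sequence
  groups but differing between them.
- **Label propagation** — spreading experimentally determined DNA-packaging
  strategies (headful, cos, DTR, host ends) across sequence clusters.
- **Synthetic data** — seeded generators with planted ground truth for every
  one of the above, used throughout the test suite.

## Core statistics

For an alignment column, each sequence *i* receives the Henikoff
position-based weight

> wᵢ ∝ Σ_columns 1 / (r · s)

where *r* is the number of distinct residue types in the column and *s* the
number of sequences sharing sequence *i*'s residue; weights are normalized
to Σ wᵢ = 1. The weighted score of a column against amino acid *x* is
Q_x = Σᵢ wᵢ S(aᵢ, x) with S the BLOSUM62 matrix, the consensus is
c = argmax_x Q_x (ties broken alphabetically), and the random-expectation
score is Q_R = Σ_b f_b Q_b over the BLOSUM62 background frequencies f_b.
Column **homogeneity** is

> H = max((Q_c − Q_R) / (S_cc − Q_R), 0) ∈ [0, 1]

H = 1 for a perfectly conserved column and H → 0 as the column approaches
the background. Trimming removes columns with > 50 % gaps or < 10 %
homogeneity.

## Worked example

```python
from terlkit.alnstats import column_stats, henikoff_weights
from terlkit.io import Msa, load_builtin_matrix

matrix = load_builtin_matrix("BLOSUM62")
msa = Msa((("seq_a", "MKVLWAALLG"),
           ("seq_b", "MKVLWAGLLG"),
           ("seq_c", "MRT-WCGPIV")))

for rid, w in zip(msa.ids, henikoff_weights(msa).weights):
    print(rid, round(w, 4))
for s in column_stats(msa, matrix)[:3]:
    print(s.column_index, s.consensus, round(s.homogeneity, 3))
```

prints

```
seq_a 0.3167
seq_b 0.2917
seq_c 0.3917
0 M 1.0
1 K 0.801
2 V 0.666
```

The divergent row (`seq_c`) receives the largest weight; the perfectly
conserved M column scores H = 1 exactly, while columns mixing dissimilar
residues fall toward 0.

The `examples/` directory contains one narrated script per capability
(`01_column_statistics.py` through `07_full_pipeline.py`); each runs in
seconds on simulated data and prints its results.

## Command line

A thin CLI wraps the library for shell pipelines:

```
terlkit trim aligned.fasta -o trimmed.fasta
terlkit classify-elements features.gff --prophages prophages.tsv
terlkit simulate family --seed 7 --out-prefix sim/fam
terlkit run --config pipeline.json
```

`terlkit run` executes the full curation pipeline from a JSON config,
writing one artifact plus a log line per stage; reruns on identical inputs
are byte-for-byte identical.

## Scope and limitations

terlkit curates and classifies; it does not infer trees. The trimmed
alignment it produces is intended as input to FastTree, IQ-TREE, or similar.
Homology hits, prophage calls, and composition-classifier labels are
consumed as input tables from external tools. The synthetic generators are
designed for planted-truth testing at desk scale, not for realistic protein
evolution; see `docs/methods.md` for their exact models and for every
numerical convention.
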