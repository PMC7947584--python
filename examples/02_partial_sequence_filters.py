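"""Partial-sequence filtering.

Removes single-domain truncations with the profile-coverage rules, checks an
alignment against its consensus, and rescues sequences by the Walker A motif.
"""

from terlkit.filters import (
    consensus_similarity_filter,
    detect_walker_a,
    domain_coverage_filter,
)
from terlkit.io import Msa, load_builtin_matrix
from terlkit.synthetic import simulate_terl_family

matrix = load_builtin_matrix("BLOSUM62")

# a simulated TerL-like family: 8 full-length proteins, 4 truncations
records, hits, truth = simulate_terl_family(
    n_full=8, n_truncated=4, length=400, divergence=0.15, seed=3
)
by_seq = {}
for h in hits:
    by_seq.setdefault(h.sequence_id, []).append(h)

print("domain-coverage filter:")
for rec in records:
    d = domain_coverage_filter(len(rec), by_seq.get(rec.id, []))
    mark = "kept  " if d.kept else "REMOVED"
    print(f"  {rec.id:16s} {mark} ({d.rule}: {d.detail})")
print(f"planted truncations: {sorted(truth.truncated_ids)}")

# every simulated sequence carries the Walker A motif at a fixed offset
print("\nWalker A detection:")
full = [r for r in records if r.id not in set(truth.truncated_ids)]
print(f"  {full[0].id}: motif at position {detect_walker_a(full[0])}")

# consensus-similarity filter on a small alignment with one junk row
msa = Msa(
    tuple((f"good_{i}", "MKVLWAGLLG") for i in range(5))
    + (("junk", "M---------"),)
)
print("\nconsensus-similarity filter:")
for d in consensus_similarity_filter(msa, matrix):
    print(f"  {d.sequence_id:8s} kept={d.kept}  ({d.detail})")
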