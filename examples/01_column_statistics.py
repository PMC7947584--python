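"""Column statistics and alignment trimming.

Computes Henikoff position-based weights, per-column homogeneity, and trims
an alignment by the joint gap/homogeneity rule.
"""

from terlkit.alnstats import column_stats, henikoff_weights, trim_alignment
from terlkit.io import Msa, load_builtin_matrix
from terlkit.synthetic import simulate_msa

matrix = load_builtin_matrix("BLOSUM62")

# a small hand alignment: two near-identical rows and one divergent one
msa = Msa(
    (
        ("seq_a", "MKVLWAALLG"),
        ("seq_b", "MKVLWAGLLG"),
        ("seq_c", "MRT-WCGPIV"),
    )
)

weights = henikoff_weights(msa)
print("sequence weights (sum to 1, divergent rows weigh more):")
for rid, w in zip(msa.ids, weights.weights):
    print(f"  {rid}: {w:.4f}")

print("\nper-column consensus and homogeneity:")
for s in column_stats(msa, matrix):
    print(
        f"  col {s.column_index:2d}  consensus={s.consensus}  "
        f"gap={s.gap_fraction:.2f}  H={s.homogeneity:.3f}"
    )

# trim a simulated alignment: gappy or heterogeneous columns are removed
noisy, _ = simulate_msa(20, 60, conservation_p=0.4, gap_p=0.3, seed=7)
trimmed, kept = trim_alignment(noisy, max_gap_fraction=0.5, min_homogeneity=0.1, matrix=matrix)
print(f"\ntrimming: {noisy.n_cols} columns -> {trimmed.n_cols} kept")
print(f"first kept columns: {kept[:10]}")
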