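"""Group-discriminative alignment sites.

Scans a two-group alignment for columns conserved within each group but
differing between them (conservation > 0.80, abundance difference >= 0.70).
"""

from terlkit.sites import report_sites, scan_discriminative_sites
from terlkit.synthetic import PlantedSite, simulate_two_group_msa

# plant two sites: a clean fixed difference and a 99%-vs-4% cysteine
# contrast modeled on a diagnostic residue position
grouped, truth = simulate_two_group_msa(
    n1=60,
    n3=40,
    n_cols=80,
    planted_sites=[
        PlantedSite(12, "K", "E", purity1=0.95, purity3=0.95),
        PlantedSite(47, "T", "C", purity1=0.59, purity3=0.99, cross1=0.04),
    ],
    seed=9,
)

calls = scan_discriminative_sites(grouped)
print(f"planted columns: {truth.planted_columns}")
print(f"retained columns: {[c.column_index for c in calls]}\n")

report = report_sites(calls, grouped, reference_row_id="g3_1")
print(report.to_string(index=False))
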