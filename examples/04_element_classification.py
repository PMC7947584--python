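"""Genomic element classification around terL genes.

Chains nearby genes into regions (gap <= 8 kb), counts distinct RcGTA-like
marker families, classifies each terL region, and applies prophage overrides.
"""

from terlkit.elements import (
    apply_prophage_override,
    calls_to_frame,
    chain_regions,
    classify_terl_regions,
)
from terlkit.synthetic import Cassette, simulate_neighborhood

# plant three cassettes: a 9-family large element, a 3-family small element
# later relabeled by an intact prophage call, and a lone terL
features, prophages, truth = simulate_neighborhood(
    [
        Cassette("chromosome", 100_000, 9),
        Cassette("chromosome", 900_000, 3, prophage="intact"),
        Cassette("plasmid_A", 20_000, 0),
    ],
    n_background=6,
    seed=5,
)

regions = chain_regions(features, max_gap=8000)
print(f"{len(features)} genes chained into {len(regions)} regions")

calls = classify_terl_regions(regions)
calls = apply_prophage_override(calls, prophages)
print(calls_to_frame(calls).to_string(index=False))
print(f"\nexpected (planted): {truth.expected_calls}")
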