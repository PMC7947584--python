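"""Packaging-strategy label propagation.

Spreads experimentally determined packaging strategies (headful, cos, dtr,
host_ends) from labeled sequences to their unlabeled cluster mates; clusters
with conflicting experimental labels are skipped with a warning.
"""

import warnings

from terlkit.labels import labels_to_frame, propagate_packaging

assignments = {
    "phage_P22": "c_headful",
    "homolog_1": "c_headful",
    "homolog_2": "c_headful",
    "phage_lambda": "c_cos",
    "homolog_3": "c_cos",
    "orphan_1": "c_orphan",
}
experimental = {"phage_P22": "headful", "phage_lambda": "cos"}

labels = propagate_packaging(assignments, experimental)
print(labels_to_frame(labels).to_string(index=False))

# a conflicting cluster is reported and left unlabeled
conflicted = {"a": "c1", "b": "c1"}
with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    out = propagate_packaging(conflicted, {"a": "headful", "b": "cos"})
print(f"\nconflicting cluster -> {len(out)} labels; warning: {caught[0].message}")
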