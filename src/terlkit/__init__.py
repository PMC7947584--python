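"""terlkit: alignment curation and gene-transfer-agent element detection
for large-terminase (TerL) protein families.

The package covers the bespoke computational steps of a TerL-scale
molecular-evolution analysis: position-based sequence weighting and
BLOSUM62 column-homogeneity trimming, partial-sequence filters, an
iterative cluster-align-merge procedure for building very large protein
alignments, chaining of RcGTA-homolog genes into genomic elements,
group-discriminative conserved-site scanning, and propagation of
experimentally determined DNA-packaging strategies across sequence
clusters.  Deterministic synthetic-data generators provide every input
class with planted ground truth.
"""

from .io import (
    GeneFeature,
    Msa,
    ProfileHit,
    SequenceRecord,
    SubstitutionMatrix,
    load_builtin_matrix,
    read_alignment,
    read_fasta,
    read_features,
    read_hits,
    write_alignment,
    write_fasta,
)
from .alnstats import (
    ColumnStats,
    WeightVector,
    column_homogeneity,
    column_score,
    column_stats,
    column_to_reference_position,
    consensus_residue,
    henikoff_weights,
    random_expectation_score,
    trim_alignment,
)
from .filters import (
    FilterDecision,
    consensus_similarity_filter,
    detect_walker_a,
    domain_coverage_filter,
    pssm_coverage_filter,
    select_representatives,
    walker_a_rescue,
)
from .iteralign import (
    IterAlignConfig,
    IterAlignResult,
    align_cluster,
    greedy_identity_cluster,
    iterate_align,
    mask_gappy_columns,
    merge_alignments,
    merge_by_guide_tree,
    profile_similarity,
    reinsert_masked,
    similarity_to_distance,
    upgma,
)
from .elements import (
    ElementCall,
    Region,
    apply_prophage_override,
    chain_regions,
    classify_terl_regions,
)
from .sites import (
    GroupedMsa,
    SiteCall,
    group_column_profile,
    report_sites,
    scan_discriminative_sites,
)
from .labels import PackagingLabel, propagate_packaging
from .pipeline import PipelineConfig, run_pipeline
from . import synthetic

__version__ = "0.1.0"
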