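# Methods

This note records the exact procedures, parameter values, and numerical
conventions implemented by terlkit, including choices the underlying methods
leave open. Problem sizes quoted for tests and examples are the package's
own desk-scale choices.

## 1. Sequence weights and column statistics (`terlkit.alnstats`)

**Henikoff position-based weights.** For each column, let *r* be the number
of distinct residue types present (gaps and ambiguity codes excluded) and
*s* the number of rows carrying a given type. Each carrying row receives
1/(r·s) for that column; raw sums are normalized so Σ wᵢ = 1. Rows with no
scorable residue anywhere are an error (the weight of such a row is
undefined), and callers that may encounter them (the consensus and coverage
filters) handle them explicitly, see §3.

**Column scores.** Q_x = Σᵢ w′ᵢ S(aᵢ, x), where the sum runs over non-gap
rows of the column and w′ renormalizes the Henikoff weights over those rows.
S is BLOSUM62. The consensus c maximizes Q_x; ties are broken
alphabetically, and a tie is declared whenever two Q values are within 1e-9
(exact ties exist — e.g. a column whose residues score two amino acids
equally — and summation order must not decide them). The random-expectation
score is Q_R = Σ_b f_b Q_b using the BLOSUM62 marginal background
frequencies (rounded to three decimals, rescaled to sum to exactly 1.000).

**Homogeneity.** H = max((Q_c − Q_R)/(S_cc − Q_R), 0), clamped to ≤ 1.
Degenerate case: if S_cc = Q_R, the column is declared H = 1 when Q_c = S_cc
and is otherwise an error. All-gap columns have no score; `column_stats`
reports them with gap fraction 1 and homogeneity 0 so trimming removes them.

**Trimming.** A column is removed if its gap fraction exceeds 0.50 **or**
its homogeneity is below 0.10 (strict inequalities; boundary columns are
kept). A `joint=True` flag switches to the AND reading for users who want
only doubly-bad columns removed; OR is the default because it matches the
procedure's curation intent.

## 2. Partial-sequence filters (`terlkit.filters`)

**Domain-coverage filter.** A sequence is kept if (a) a full-profile hit
covers ≥ 75 % of the profile, or (b) it has a single-domain match covering
≥ 75 % of an N- or C-terminal domain profile while ≥ 35 % of the sequence
length remains on the side of the missing domain. Partial full-profile hits
are assigned to the N- or C-terminal side by the midpoint of their profile
span (an operational rule; the source procedure does not specify one).
Thresholds are inclusive.

**Consensus-similarity filter.** The row score is Σ S(aᵢ, cᵢ) over columns
where the consensus is defined and the row carries a residue. The perfect
score is Σ S(cᵢ, cᵢ) — row-independent, so the threshold (row score ≥ 10 %
of perfect, inclusive) is a fixed bar per alignment. Rows with no residues
cannot enter the weight computation; the consensus is computed from the
occupied rows and empty rows score 0, i.e. they are removed.

**PSSM-coverage filter.** A row must carry residues in ≥ 75 % (inclusive)
of the consensus-defined columns. Kept rows are also returned as extracted
sequences spanning the first through last consensus-defined column.

**Walker A rescue.** Sequences ≥ 300 residues with a hit at E ≤ 1e-3 and a
match to `[AG].{4}GK[ST]` are retained regardless of coverage.

**Representatives.** Within a cluster, members sort by (length, id) and the
lower-middle element is taken — deterministic for even-sized clusters.

## 3. Iterative alignment (`terlkit.iteralign`)

1. **Clustering.** Sequences sort by (length desc, id); each becomes a
   centroid or joins the first centroid with pairwise identity ≥ 0.5.
   Identity = identities / alignment length from a global Biopython
   alignment (BLOSUM62, gap open 10, extend 1).
2. **Within-cluster alignment.** Progressive profile–profile alignment in
   UPGMA order using a Gotoh affine-gap DP over column frequency profiles
   (column score Σ_a Σ_b p_A(a) S(a,b) p_B(b); open 10, extend 1; traceback
   via pointer matrices with tie preference match > gap-in-A > gap-in-B).
3. **Block merging.** Columns with > 67 % gaps are masked (fragments keyed
   by the count of preceding unmasked residues, reinserted afterwards);
   block similarity is DP(A,B)/√(DP(A,A)·DP(B,B)) clamped to [0,1];
   distance d = −ln(max(sim, 1e-6)); blocks join when their UPGMA node
   height (d/2) is ≤ the depth threshold 2.3. Iterate (≤ 20 times) until
   one block remains or no merge happens.

The procedure maintains one invariant checked everywhere: degapping the
alignment reproduces the input sequences exactly. The depth threshold and
gap-mask fraction are plain configuration values; no equivalence to any
external program's scale is claimed. Unrelated families (profile similarity
near 0) hit the distance floor −ln(1e-6) ≈ 13.8 and correctly never merge.

**UPGMA.** Hand-written, average-linkage, height = d/2. The merge pair
minimizes (distance, lexicographically smallest member labels), making tree
shape independent of input order. Input matrices must be symmetric,
non-negative, zero-diagonal, NaN-free.

## 4. Element classification (`terlkit.elements`)

Genes on the same replicon chain into a region when the gap to the running
maximum end is ≤ 8000 bp (1-D single linkage; equivalent to transitive
closure of the pairwise gap relation, which the tests verify directly).
For each region containing a terL gene, the number of **distinct** counted
marker families (g3–g9, g12–g15; terL itself never counts) among
RcGTA-like-labeled genes determines the call: ≥ 6 large element, 1–5 small,
0 none. External prophage calls override: an intact prophage supersedes
small/none; a questionable one only none; a large element is never
overridden. Coordinates are 1-based inclusive; the gap between abutting
genes is 0.

## 5. Discriminative sites (`terlkit.sites`)

For each column and each of two groups, the modal residue and its abundance
are computed over non-gap rows (modal ties alphabetical). Columns where
either group is > 50 % gapped are skipped. A column is a candidate when a
group's modal abundance is **strictly** > 0.80; it is retained when the
between-group difference in that residue's abundance is ≥ 0.70
(**inclusive**). Both directions are tested; the reported difference is the
maximum over passing directions. The 99 %-vs-4 % cysteine contrast that
motivates the method yields difference 0.95 and is retained; an exact
0.80-conservation column is rejected by the strict bound.

## 6. Label propagation (`terlkit.labels`)

Experimental packaging-strategy labels (headful, cos, dtr, host_ends)
propagate to unlabeled members of the same cluster; each propagated label
names its source (the alphabetically first labeled member). A cluster with
conflicting experimental labels emits a warning and contributes nothing.
Propagation is idempotent.

## 7. Synthetic generators (`terlkit.synthetic`)

All generators are pure functions of their arguments, seeded via
`numpy.random.default_rng`, and return ground-truth objects alongside data.

- `simulate_msa` — independent columns, conserved with probability
  `conservation_p`, gapped with `gap_p`; rows left empty get one residue
  restored so weights stay defined.
- `simulate_two_group_msa` — identical across groups except at planted
  sites. Purities are realized as **exact counts** `round(p·n)` so
  threshold boundaries are deterministic, not binomially fuzzy; `cross`
  fields plant the other group's residue at a controlled abundance.
- `simulate_terl_family` — a root with a fixed Walker A motif; descendants
  substitute non-motif sites at the divergence rate; truncations keep the
  N- or C-terminal 55 %; the hit table encodes full-profile hits for full
  sequences and single-domain hits for truncations.
- `simulate_related_families` — subfamilies descending from one root at a
  between-family divergence, then within-family divergence; the regime in
  which iterative merging is expected to succeed.
- `simulate_neighborhood` — cassettes of terL plus n distinct marker genes
  at sub-threshold spacing, background genes ≥ 20 kb away, optional planted
  prophage spans; the ground truth includes the effect of the planted
  prophage override.

The generators model none of: realistic indel processes, rate heterogeneity,
phylogenetic correlation beyond the single root, or genome composition. They
exist to make planted truth recoverable exactly.

## 8. Numerical conventions

- Alphabet: the 20 standard amino acids; `X B Z U J O *` are ambiguity
  codes, excluded (like gaps) from weights, scores, and abundances.
- All thresholds are inclusive unless stated strict above; the two strict
  bounds are the trim rules (> 50 % gaps, < 10 % homogeneity) and the site
  conservation bound (> 0.80).
- Tie-breaks are always deterministic: alphabetical for residues (with the
  1e-9 tolerance of §1), lexicographic labels for UPGMA, (length, id) sort
  orders elsewhere.
- Floating-point comparisons in degenerate-case detection use 1e-12.
- The pipeline writes its configuration and per-stage logs; reruns on
  identical inputs are byte-for-byte identical, which the test suite checks
  at the artifact level.

## 9. Limitations

- Profile–profile alignment is O(L²) per pair and pure Python/NumPy; it is
  intended for hundreds, not hundreds of thousands, of sequences.
- Homology searching, prophage detection, and composition classification
  are out of scope; their outputs are consumed as tables.
- The guide tree is a merge-order heuristic, not a phylogeny.
- Element classification trusts input gene labels; mislabeled families
  propagate directly into calls.
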