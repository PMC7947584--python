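"""Iterative cluster-align-merge construction of a family-wide alignment.

The procedure builds one large protein alignment from thousands of diverged
homologs without ever aligning them all at once:

1. greedy centroid clustering at a fractional-identity threshold;
2. progressive alignment within each cluster;
3. temporary removal of columns with more than 67% gaps;
4. all-vs-all similarity between cluster alignments (profile-profile
   dynamic programming, normalized to [0, 1]);
5. a UPGMA guide tree over -ln(similarity) distances;
6. profile-profile merging of every guide-tree node whose height lies at or
   below a depth threshold;
7. reinsertion of the masked columns;
8. repeat with the merged blocks as the new clusters until a single block
   remains or no merge makes progress.

The aligner, similarity scorer and clusterer are deliberately simple,
deterministic stand-ins for the external tools a production run would plug
in (UCLUST/MMseqs2, MUSCLE/MAFFT, HHsearch/HHalign); each is exposed behind
a small function surface so a wrapper around the external binary can be
substituted.  The invariant the whole machine preserves is sequence
conservation: degapping any row of any block at any iteration reproduces
the input residues exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align as _bioalign

from .io import AA_INDEX, GAP, Msa, SequenceRecord, SubstitutionMatrix, load_builtin_matrix

SIMILARITY_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# greedy centroid clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSet:
    """Assignment of every input sequence to exactly one cluster."""

    assignments: dict[str, str]
    threshold: float


def _make_pairwise_aligner(matrix: SubstitutionMatrix):
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    from Bio.Align import substitution_matrices

    aligner.substitution_matrix = substitution_matrices.load(matrix.name)
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str, aligner=None) -> float:
    """Fractional identity of a global pairwise alignment:
    matches / alignment length."""
    if aligner is None:
        aligner = _make_pairwise_aligner(load_builtin_matrix("BLOSUM62"))
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def greedy_identity_cluster(
    records: list[SequenceRecord],
    threshold: float,
    matrix: SubstitutionMatrix | None = None,
) -> ClusterSet:
    """Length-sorted greedy centroid clustering.

    Sequences are visited by decreasing length (ties by id); each joins the
    first existing centroid whose global-alignment fractional identity is at
    least ``threshold``, otherwise it opens a new centroid.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    if matrix is None:
        matrix = load_builtin_matrix("BLOSUM62")
    aligner = _make_pairwise_aligner(matrix)
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    centroids: list[SequenceRecord] = []
    assignments: dict[str, str] = {}
    for rec in ordered:
        placed = False
        for cen in centroids:
            if pairwise_identity(cen.residues, rec.residues, aligner) >= threshold:
                assignments[rec.id] = cen.id
                placed = True
                break
        if not placed:
            centroids.append(rec)
            assignments[rec.id] = rec.id
    return ClusterSet(assignments, threshold)


# ---------------------------------------------------------------------------
# profile-profile dynamic programming
# ---------------------------------------------------------------------------

def _profile_frequencies(msa: Msa) -> np.ndarray:
    """(L, 20) per-column residue frequencies; gaps contribute nothing, so
    column vectors of gappy columns sum to less than 1."""
    idx = msa.to_indices()
    n, L = idx.shape
    freqs = np.zeros((L, 20))
    for j in range(L):
        col = idx[:, j]
        present = col >= 0
        if present.any():
            freqs[j] = np.bincount(col[present], minlength=20) / n
    return freqs


def _gotoh_profile_dp(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    matrix: SubstitutionMatrix,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[float, list[str]]:
    """Global affine-gap alignment of two column-frequency profiles.

    Column pair score: sum_a sum_b pA(a) pB(b) S(a, b).  Returns the optimal
    score and the traceback path as a list of 'M' (column pair), 'A' (column
    of A against gap), 'B' (column of B against gap).  Tie preference
    M > A > B makes the traceback deterministic.
    """
    La, Lb = len(freq_a), len(freq_b)
    C = freq_a @ matrix.scores @ freq_b.T
    NEG = -1e30
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap in B (consumes a column of A)
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in A (consumes a column of B)
    # predecessor state of each cell: 0=M, 1=X, 2=Y
    ptr_m = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptr_x = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptr_y = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, Lb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
        ptr_y[0, j] = 0 if j == 1 else 2
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(prev))  # ties prefer M > X > Y
            M[i, j] = C[i - 1, j - 1] + prev[k]
            ptr_m[i, j] = k
            open_x, ext_x = M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend
            if open_x >= ext_x:
                X[i, j], ptr_x[i, j] = open_x, 0
            else:
                X[i, j], ptr_x[i, j] = ext_x, 1
            open_y, ext_y = M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i, j], ptr_y[i, j] = open_y, 0
            else:
                Y[i, j], ptr_y[i, j] = ext_y, 2
    i, j = La, Lb
    finals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(finals))
    best = finals[state]
    path: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            path.append("M")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append("A")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            path.append("B")
            state = int(ptr_y[i, j])
            j -= 1
    path.reverse()
    return float(best), path


def merge_alignments(
    msa_a: Msa,
    msa_b: Msa,
    matrix: SubstitutionMatrix,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Profile-profile merge of two alignments into one, following the
    optimal Gotoh path; rows of A precede rows of B."""
    _, path = _gotoh_profile_dp(
        _profile_frequencies(msa_a), _profile_frequencies(msa_b), matrix, gap_open, gap_extend
    )
    rows_a = {rid: [] for rid in msa_a.ids}
    rows_b = {rid: [] for rid in msa_b.ids}
    ia = ib = 0
    for step in path:
        if step == "M":
            for rid, seq in msa_a.records:
                rows_a[rid].append(seq[ia])
            for rid, seq in msa_b.records:
                rows_b[rid].append(seq[ib])
            ia += 1
            ib += 1
        elif step == "A":
            for rid, seq in msa_a.records:
                rows_a[rid].append(seq[ia])
            for rid in rows_b:
                rows_b[rid].append(GAP)
            ia += 1
        else:
            for rid in rows_a:
                rows_a[rid].append(GAP)
            for rid, seq in msa_b.records:
                rows_b[rid].append(seq[ib])
            ib += 1
    records = tuple(
        (rid, "".join(rows_a[rid])) for rid, _ in msa_a.records
    ) + tuple((rid, "".join(rows_b[rid])) for rid, _ in msa_b.records)
    return Msa(records)


def profile_similarity(
    msa_a: Msa, msa_b: Msa, matrix: SubstitutionMatrix | None = None
) -> float:
    """Normalized profile-profile similarity in [0, 1].

    The optimal profile DP score of A vs B divided by the geometric mean of
    the self-scores DP(A,A) and DP(B,B); symmetric, and sim(A, A) = 1.
    """
    if matrix is None:
        matrix = load_builtin_matrix("BLOSUM62")
    fa, fb = _profile_frequencies(msa_a), _profile_frequencies(msa_b)
    s_ab, _ = _gotoh_profile_dp(fa, fb, matrix)
    s_aa, _ = _gotoh_profile_dp(fa, fa, matrix)
    s_bb, _ = _gotoh_profile_dp(fb, fb, matrix)
    if s_aa <= 0 or s_bb <= 0:
        return 0.0
    sim = s_ab / math.sqrt(s_aa * s_bb)
    return min(max(sim, 0.0), 1.0)


def similarity_to_distance(sim: float) -> float:
    """d = -ln(max(sim, 1e-6)): 0 at similarity 1, floored at -ln(1e-6)."""
    if not 0 <= sim <= 1:
        raise ValueError(f"similarity {sim} outside [0, 1]")
    return -math.log(max(sim, SIMILARITY_FLOOR))


# ---------------------------------------------------------------------------
# progressive alignment of one cluster
# ---------------------------------------------------------------------------

def align_cluster(
    records: list[SequenceRecord],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Progressive alignment of a set of sequences.

    Pairwise identity distances feed a UPGMA tree whose post-order guides
    successive profile-profile merges.  Degapping the result recovers the
    inputs exactly.
    """
    if not records:
        raise ValueError("no records to align")
    if matrix is None:
        matrix = load_builtin_matrix("BLOSUM62")
    if len(records) == 1:
        return Msa(((records[0].id, records[0].residues),))
    aligner = _make_pairwise_aligner(matrix)
    ids = [r.id for r in records]
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(records[i].residues, records[j].residues, aligner)
            dist[i, j] = dist[j, i] = 1.0 - ident
    tree = upgma(dist, ids)
    blocks = {
        r.id: Msa(((r.id, r.residues),)) for r in records
    }

    def _merge(node: TreeNode) -> Msa:
        if node.is_leaf:
            return blocks[node.label]
        merged = _merge(node.children[0])
        for child in node.children[1:]:
            merged = merge_alignments(merged, _merge(child), matrix, gap_open, gap_extend)
        return merged

    out = _merge(tree)
    # restore input row order
    order = {rid: k for k, rid in enumerate(ids)}
    rows = tuple(sorted(out.records, key=lambda rs: order[rs[0]]))
    return Msa(rows)


# ---------------------------------------------------------------------------
# UPGMA guide tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted ultrametric guide tree."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        def _fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6f}"
            inner = ",".join(_fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6f}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(_fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(distance_matrix: np.ndarray, labels: list[str]) -> TreeNode:
    """Standard UPGMA agglomeration.

    Cluster distances are arithmetic means over member pairs; the node for a
    merge at distance d sits at height d/2.  Ties break on the smallest
    lexicographic pair of minimal leaf labels, making the tree deterministic.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
    nodes: dict[int, TreeNode] = {i: TreeNode(0.0, label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minlabel = {i: labels[i] for i in range(n)}
    dist = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        # smallest distance; ties by lexicographic (minlabel_i, minlabel_j)
        best_pair = min(
            dist,
            key=lambda p: (
                dist[p],
                *sorted((minlabel[p[0]], minlabel[p[1]])),
            ),
        )
        i, j = best_pair
        d = dist[best_pair]
        new = TreeNode(d / 2.0, children=(nodes[i], nodes[j]))
        new_size = sizes[i] + sizes[j]
        new_min = min(minlabel[i], minlabel[j])
        # average distances to the new cluster
        new_dists = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dists[k] = (dik * sizes[i] + djk * sizes[j]) / new_size
        for k in (i, j):
            del nodes[k], sizes[k], minlabel[k]
        dist = {
            p: v for p, v in dist.items() if i not in p and j not in p
        }
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        nodes[next_id] = new
        sizes[next_id] = new_size
        minlabel[next_id] = new_min
        next_id += 1
    return next(iter(nodes.values()))


# ---------------------------------------------------------------------------
# gappy-column masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskRecord:
    """Residues temporarily removed from each row, keyed by the count of
    unmasked residues preceding them in that row's ungapped sequence."""

    insertions: dict[str, tuple[tuple[int, str], ...]]


def mask_gappy_columns(msa: Msa, max_gap: float = 0.67) -> tuple[Msa, MaskRecord]:
    """Temporarily remove columns with strictly more than ``max_gap`` gaps.

    Returns the masked alignment and a record sufficient to restore every
    removed residue with :func:`reinsert_masked`.
    """
    n = msa.n_rows
    masked_cols = set()
    for j in range(msa.n_cols):
        col = msa.column(j)
        if col.count(GAP) / n > max_gap:
            masked_cols.add(j)
    if not masked_cols:
        return msa, MaskRecord({})
    kept_cols = [j for j in range(msa.n_cols) if j not in masked_cols]
    insertions: dict[str, tuple[tuple[int, str], ...]] = {}
    rows = []
    for rid, seq in msa.records:
        kept_seq = "".join(seq[j] for j in kept_cols)
        # record masked residues by preceding unmasked-residue count
        per_row: dict[int, list[str]] = {}
        unmasked_before = 0
        for j in range(msa.n_cols):
            ch = seq[j]
            if j in masked_cols:
                if ch != GAP:
                    per_row.setdefault(unmasked_before, []).append(ch)
            elif ch != GAP:
                unmasked_before += 1
        if per_row:
            insertions[rid] = tuple(
                (k, "".join(v)) for k, v in sorted(per_row.items())
            )
        rows.append((rid, kept_seq))
    masked = Msa(tuple(rows))
    if any(len(s.replace(GAP, "")) == 0 for _, s in rows):
        # a row living entirely in masked columns would vanish; keep one
        # placeholder impossible -> reject
        raise ValueError("masking removed every residue of a row; lower max_gap")
    return masked, MaskRecord(insertions)


def reinsert_masked(msa: Msa, mask: MaskRecord) -> Msa:
    """Reinsert masked residues as unaligned insertion columns.

    Each row's removed fragments return immediately after the unmasked
    residue that preceded them; other rows receive gaps in the new columns.
    Degapping any row of the result reproduces its original sequence.
    """
    unknown = set(mask.insertions) - set(msa.ids)
    if unknown:
        raise ValueError(f"mask record names unknown rows {sorted(unknown)}")
    if not mask.insertions:
        return msa
    # For each row, map insertion key (residue count) -> fragment.
    frag_of = {rid: dict(items) for rid, items in mask.insertions.items()}
    new_rows: dict[str, list[str]] = {rid: [] for rid in msa.ids}
    order = list(msa.ids)
    # residue counters per row
    counts = {rid: 0 for rid in msa.ids}

    def _emit_insertions_at_current_counts() -> None:
        # Insertions from different rows occupy separate column blocks,
        # emitted in row order for determinism.
        for rid in order:
            frag = frag_of.get(rid, {}).pop(counts[rid], None)
            if frag:
                for other in order:
                    new_rows[other].append(frag if other == rid else GAP * len(frag))

    _emit_insertions_at_current_counts()
    for j in range(msa.n_cols):
        col = {rid: msa.row(rid)[j] for rid in order}
        for rid in order:
            new_rows[rid].append(col[rid])
        advanced = [rid for rid in order if col[rid] != GAP]
        for rid in advanced:
            counts[rid] += 1
        _emit_insertions_at_current_counts()
    leftovers = {rid: d for rid, d in frag_of.items() if d}
    if leftovers:
        raise ValueError(
            f"mask record inconsistent with alignment: unplaced fragments for "
            f"{sorted(leftovers)}"
        )
    rows = tuple((rid, "".join(new_rows[rid])) for rid in order)
    return Msa(rows)


# ---------------------------------------------------------------------------
# guide-tree-driven merging and the outer iteration
# ---------------------------------------------------------------------------

@dataclass
class AlignmentState:
    """Blocks (cluster alignments) at one point of the iteration."""

    iteration: int
    blocks: list[Msa]

    @property
    def block_ids(self) -> list[str]:
        return [min(b.ids) for b in self.blocks]


def merge_by_guide_tree(
    state: AlignmentState,
    tree: TreeNode,
    depth_threshold: float,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentState:
    """Merge blocks at guide-tree nodes whose height is at or below
    ``depth_threshold``; deeper (higher) nodes leave their subtrees as
    separate blocks."""
    if matrix is None:
        matrix = load_builtin_matrix("BLOSUM62")
    by_id = {bid: blk for bid, blk in zip(state.block_ids, state.blocks)}
    unknown = set(tree.leaves()) - set(by_id)
    if unknown:
        raise ValueError(f"guide tree names unknown blocks {sorted(unknown)}")

    out_blocks: list[Msa] = []

    def _walk(node: TreeNode) -> None:
        if node.is_leaf:
            out_blocks.append(by_id[node.label])
            return
        if node.height <= depth_threshold:
            out_blocks.append(_merge_subtree(node))
        else:
            for c in node.children:
                _walk(c)

    def _merge_subtree(node: TreeNode) -> Msa:
        if node.is_leaf:
            return by_id[node.label]
        merged = _merge_subtree(node.children[0])
        for c in node.children[1:]:
            merged = merge_alignments(merged, _merge_subtree(c), matrix, gap_open, gap_extend)
        return merged

    _walk(tree)
    return AlignmentState(state.iteration, out_blocks)


@dataclass
class IterAlignConfig:
    """Knobs of the iterative alignment procedure."""

    cluster_threshold: float = 0.5
    depth_threshold: float = 2.3
    max_iterations: int = 20
    max_gap_mask: float = 0.67
    gap_open: float = 10.0
    gap_extend: float = 1.0
    matrix_name: str = "BLOSUM62"


@dataclass
class IterAlignResult:
    alignment: Msa
    unaligned_ids: list[str]
    iterations: int
    block_counts: list[int]
    converged: bool


def iterate_align(
    records: list[SequenceRecord], config: IterAlignConfig | None = None
) -> IterAlignResult:
    """Run the full cluster-align-merge loop.

    Returns the largest final block, the ids left outside it, the number of
    iterations used, and the per-iteration block counts.  Terminates early
    with ``converged=False`` when an iteration with more than one block
    makes no merge progress.
    """
    if not records:
        raise ValueError("no records to align")
    cfg = config or IterAlignConfig()
    matrix = load_builtin_matrix(cfg.matrix_name)

    clusters = greedy_identity_cluster(records, cfg.cluster_threshold, matrix)
    by_cluster: dict[str, list[SequenceRecord]] = {}
    for rec in sorted(records, key=lambda r: r.id):
        by_cluster.setdefault(clusters.assignments[rec.id], []).append(rec)
    blocks = [
        align_cluster(members, matrix, cfg.gap_open, cfg.gap_extend)
        for _, members in sorted(by_cluster.items())
    ]
    state = AlignmentState(0, blocks)
    block_counts = [len(blocks)]
    converged = len(blocks) == 1

    for it in range(1, cfg.max_iterations + 1):
        if len(state.blocks) == 1:
            converged = True
            break
        masked_blocks: list[Msa] = []
        masks: list[MaskRecord] = []
        for blk in state.blocks:
            mb, mk = mask_gappy_columns(blk, cfg.max_gap_mask)
            masked_blocks.append(mb)
            masks.append(mk)
        mstate = AlignmentState(it, masked_blocks)
        ids = mstate.block_ids
        k = len(ids)
        D = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                sim = profile_similarity(masked_blocks[i], masked_blocks[j], matrix)
                D[i, j] = D[j, i] = similarity_to_distance(sim)
        tree = upgma(D, ids)
        merged = merge_by_guide_tree(
            mstate, tree, cfg.depth_threshold, matrix, cfg.gap_open, cfg.gap_extend
        )
        # reinsert all masked residues into whichever block their row landed in
        combined_mask: dict[str, tuple[tuple[int, str], ...]] = {}
        for mk in masks:
            combined_mask.update(mk.insertions)
        restored: list[Msa] = []
        for blk in merged.blocks:
            sub = MaskRecord(
                {rid: ins for rid, ins in combined_mask.items() if rid in set(blk.ids)}
            )
            restored.append(reinsert_masked(blk, sub))
        if len(restored) >= len(state.blocks):
            state = AlignmentState(it, restored)
            block_counts.append(len(restored))
            converged = len(restored) == 1
            break
        state = AlignmentState(it, restored)
        block_counts.append(len(restored))
        converged = len(restored) == 1

    largest = max(state.blocks, key=lambda b: (b.n_rows, min(b.ids)))
    unaligned = sorted(
        rid for blk in state.blocks if blk is not largest for rid in blk.ids
    )
    return IterAlignResult(largest, unaligned, state.iteration, block_counts, converged)
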