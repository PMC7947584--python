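import numpy as np
import pytest

from terlkit.io import AMINO_ACIDS, Msa, load_builtin_matrix


@pytest.fixture(scope="session")
def blosum62():
    return load_builtin_matrix("BLOSUM62")


@pytest.fixture()
def small_msa():
    return Msa((("a", "AA"), ("b", "AC"), ("c", "CC")))


def random_msa(rng: np.random.Generator, n_rows: int, n_cols: int, gap_p: float = 0.2) -> Msa:
    """Small random MSA for oracle tests; every row keeps >= 1 residue."""
    rows = []
    for i in range(n_rows):
        while True:
            chars = [
                "-" if rng.random() < gap_p else AMINO_ACIDS[rng.integers(20)]
                for _ in range(n_cols)
            ]
            if any(c != "-" for c in chars):
                break
        rows.append((f"s{i + 1}", "".join(chars)))
    return Msa(tuple(rows))


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the library internals
# ---------------------------------------------------------------------------

def brute_henikoff(msa: Msa) -> list[float]:
    """Literal transcription of the position-based weighting rule."""
    n, L = msa.n_rows, msa.n_cols
    raw = [0.0] * n
    for j in range(L):
        col = [seq[j] for _, seq in msa.records]
        residues = [c for c in col if c in AMINO_ACIDS]
        if not residues:
            continue
        types = sorted(set(residues))
        r = len(types)
        for i, c in enumerate(col):
            if c in AMINO_ACIDS:
                s = residues.count(c)
                raw[i] += 1.0 / (r * s)
    total = sum(raw)
    return [x / total for x in raw]


def brute_column_q(msa: Msa, weights: list[float], j: int, matrix) -> dict[str, float]:
    """All 20 Q_x by direct weighted sums with per-column renormalization."""
    col = [seq[j] for _, seq in msa.records]
    pairs = [(w, c) for w, c in zip(weights, col) if c in AMINO_ACIDS]
    wsum = sum(w for w, _ in pairs)
    out = {}
    for x in AMINO_ACIDS:
        out[x] = sum(w / wsum * matrix.score(c, x) for w, c in pairs)
    return out


def brute_homogeneity(msa: Msa, j: int, matrix) -> float:
    """Re-derive weights and all 20 column scores, then compose H."""
    w = brute_henikoff(msa)
    q = brute_column_q(msa, w, j, matrix)
    # alphabetical tie-break; ties are detected with a tolerance because
    # exact Q ties exist and summation order must not decide them
    best = max(q.values())
    c = min(x for x in q if q[x] >= best - 1e-9)
    qc = q[c]
    qr = sum(matrix.background[AMINO_ACIDS.index(b)] * q[b] for b in AMINO_ACIDS)
    scc = matrix.score(c, c)
    if abs(scc - qr) < 1e-12:
        return 1.0
    return max((qc - qr) / (scc - qr), 0.0)
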