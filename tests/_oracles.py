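"""Independent brute-force oracles used only by the test suite.

Deliberately naive, pure-Python implementations: full-matrix affine-gap local
alignment scoring, a hard-coded codon table, and exhaustive scans.  They share
no code with the package's alignment path.
"""

# standard genetic code, bases in TCAG order (T=0, C=1, A=2, G=3)
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_B = {"T": 0, "C": 1, "A": 2, "G": 3}


def oracle_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        c = seq[i : i + 3]
        try:
            out.append(_AA[16 * _B[c[0]] + 4 * _B[c[1]] + _B[c[2]]])
        except KeyError:
            out.append("X")
    return "".join(out)


def oracle_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def naive_local_affine(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score, three-matrix DP, gap cost open + L*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            d = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, d, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def nt_score_fn(match: float, mismatch: float):
    def fn(x, y):
        if x == "N" or y == "N":
            return mismatch
        return match if x == y else mismatch

    return fn


def blosum62_score_fn(stop_score: float = -1000.0):
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alpha = "".join(mat.alphabet)

    def fn(x, y):
        if x == "*" or y == "*":
            return stop_score
        if x not in alpha:
            x = "X"
        if y not in alpha:
            y = "X"
        return float(mat[alpha.index(x), alpha.index(y)])

    return fn


def naive_translated_best(nt_query: str, protein: str, score_fn, gap_open, gap_extend) -> float:
    """Best score over all six reading frames, via the naive local DP."""
    best = 0.0
    rc = oracle_revcomp(nt_query)
    for src in (nt_query, rc):
        for off in range(3):
            pep = oracle_translate(src[off:])
            if pep:
                best = max(best, naive_local_affine(pep, protein, score_fn, gap_open, gap_extend))
    return best


def naive_best_hit_table(queries, targets, score_of) -> dict:
    """Exhaustive best-target-per-query scan; score_of(qid, tid) -> (score, cols).

    Ties resolved by highest score, then longest alignment, then smallest id.
    """
    out = {}
    for q in queries:
        ranked = sorted(
            ((score_of(q, t), t) for t in targets),
            key=lambda st: (-st[0][0], -st[0][1], st[1]),
        )
        out[q] = ranked[0][1]
    return out
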