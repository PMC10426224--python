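"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's alignment/scanning code paths:
plain-python dynamic programming over character-keyed scoring functions,
naive double-loop substring matching, and direct count tables.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = -(10 ** 9)


def blosum_scorer(name: str):
    mat = substitution_matrices.load(name)
    letters = set(mat.alphabet) - {"*"}

    def score(a: str, b: str) -> int:
        if a in letters and b in letters:
            return int(mat[a, b])
        return -1

    return score


def nuc_scorer(match: int = 5, mismatch: int = -4):
    def score(a: str, b: str) -> int:
        if a in "ACGT" and b in "ACGT":
            return match if a == b else mismatch
        return -1

    return score


def ref_local_align(q: str, s: str, score, gap_open: int, gap_extend: int,
                    identity_eligible: frozenset[str]) -> dict:
    """Plain quadratic-space affine-gap local DP with the documented
    tie-break: end cell = max score with smallest subject end then smallest
    query end; moves prefer diagonal, then gap-in-subject, then gap-in-query;
    gap closure preferred over extension."""
    m, n = len(q), len(s)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + score(q[i - 1], s[j - 1]),
                          E[i][j], F[i][j])

    best = max(max(row) for row in H)
    if best == 0:
        return {"score": 0, "columns": 0, "identities": 0}
    end = min((j, i) for i in range(m + 1) for j in range(n + 1)
              if H[i][j] == best)
    j, i = end
    cols = identities = 0
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if H[i][j] == H[i - 1][j - 1] + score(q[i - 1], s[j - 1]):
                cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] in identity_eligible:
                    identities += 1
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols += 1
            state = "H" if F[i][j] == H[i - 1][j] - gap_open - gap_extend \
                else "F"
            i -= 1
        else:
            cols += 1
            state = "H" if E[i][j] == H[i][j - 1] - gap_open - gap_extend \
                else "E"
            j -= 1
    return {"score": best, "columns": cols, "identities": identities}


def naive_shared_kmers(query: str, subject: str, k: int) -> dict:
    """O(n*m*k) double-loop scan -> {kmer: (query starts, subject starts)}."""
    out: dict[str, tuple[list[int], list[int]]] = {}
    for i in range(len(query) - k + 1):
        kmer = query[i:i + k]
        if "X" in kmer:
            continue
        for j in range(len(subject) - k + 1):
            if subject[j:j + k] == kmer:
                qpos, spos = out.setdefault(kmer, ([], []))
                if i not in qpos:
                    qpos.append(i)
                if j not in spos:
                    spos.append(j)
    return out


def count_table(s: str, k: int = 2) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        out[s[i:i + k]] = out.get(s[i:i + k], 0) + 1
    return out
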