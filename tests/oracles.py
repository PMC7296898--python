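"""Independent brute-force oracles, deliberately naive.

Kept separate from the package so oracle and implementation share no
code paths.
"""

from __future__ import annotations

START = {"ATG", "GTG", "TTG"}
STOP = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(seq: str, min_len: int = 90) -> set[tuple[int, int, str]]:
    """All (start, end, strand) longest-per-stop ORFs by naive codon walking.

    For every start codon, walk codon-by-codon to the first in-frame
    stop; group candidates by their stop and keep the longest (earliest
    start).  Coordinates are 0-based half-open on the forward strand.
    """
    n = len(seq)
    out: set[tuple[int, int, str]] = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        best_start: dict[int, int] = {}  # stop_end -> min start
        for i in range(n - 2):
            if s[i : i + 3] not in START:
                continue
            j = i
            while j + 3 <= n:
                if s[j : j + 3] in STOP:
                    end = j + 3
                    if end - i >= min_len:
                        if end not in best_start or i < best_start[end]:
                            best_start[end] = i
                    break
                j += 3
        for end, start in best_start.items():
            if strand == "+":
                out.add((start, end, "+"))
            else:
                out.add((n - end, n - start, "-"))
    return out


def sw_score(a: str, b: str, match=2, mismatch=-3, open_=-5, extend=-2) -> float:
    """Smith-Waterman optimal local score, affine gaps (Gotoh, full DP).

    A gap of length k costs open_ + (k-1)*extend.
    """
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s)
            if M[i][j] > best:
                best = M[i][j]
    return best
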