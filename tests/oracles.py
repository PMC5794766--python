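"""Independent brute-force oracles used to cross-check the library.

These deliberately share no code with the implementations they check:
the shared-substring oracle walks every diagonal of the comparison matrix;
the alignment oracle is a plain affine-gap dynamic program; the ORF oracle
scans every position; the window oracle enumerates every (start, length)
pair.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_shared_sense(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal shared substrings >= k, sense only, by diagonal run scan.

    N matches nothing. Returns sorted (pos_a, pos_b, length)."""
    out: list[tuple[int, int, int]] = []
    la, lb = len(a), len(b)
    for d in range(-(lb - 1), la):
        run = 0
        for j in range(lb + 1):
            i = j + d
            ok = j < lb and 0 <= i < la and a[i] == b[j] and a[i] != "N"
            if ok:
                run += 1
            else:
                if run >= k:
                    out.append(((j - run) + d, j - run, run))
                run = 0
    return sorted(out)


def brute_shared_both(a: str, b: str, k: int) -> list[tuple[int, int, int, str]]:
    """Sense plus reverse-complement matches; revcomp pos_b mapped back to
    b's forward strand."""
    out = [(i, j, ln, "sense") for i, j, ln in brute_shared_sense(a, b, k)]
    rc = revcomp(b)
    for i, j, ln in brute_shared_sense(a, rc, k):
        out.append((i, len(b) - (j + ln), ln, "revcomp"))
    return sorted(out)


def brute_longest_shared(a: str, b: str) -> int:
    best = 0
    for _, _, ln in brute_shared_sense(a, b, 1):
        best = max(best, ln)
    return best


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_local_align_score(q: str, s: str, gap_open: float = 11.0,
                            gap_extend: float = 1.0) -> float:
    """Smith-Waterman best score with affine gaps, three-state DP.

    Gap of length L costs gap_open + (L - 1) * gap_extend, matching the
    aligner convention where opening a gap scores -gap_open and each
    extension -gap_extend.
    """
    n, m = len(q), len(s)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # match/mismatch state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in s (consume q)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in q (consume s)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = float(_BLOSUM62[q[i - 1]][s[j - 1]])
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub)
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


_STOPS = {"TAA", "TAG", "TGA"}


def brute_orfs(seq: str, min_len: int) -> set[tuple[int, int, str]]:
    """All complete ATG..stop spans >= min_len on both strands, as forward
    coordinates (start, end, strand)."""
    found: set[tuple[int, int, str]] = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= n:
                codon = s[j : j + 3]
                if codon in _STOPS:
                    if j + 3 - i >= min_len:
                        if strand == "+":
                            found.add((i, j + 3, "+"))
                        else:
                            found.add((n - (j + 3), n - i, "-"))
                    break
                j += 3
    return found


def brute_windows(seq: str, orf_start: int, orf_end: int,
                  len_min: int = 200, len_max: int = 500,
                  gc_min: float = 40.0, gc_max: float = 60.0,
                  margin: int = 70) -> set[tuple[int, int]]:
    """Every (start, end) window satisfying the design constraints, by
    exhaustive enumeration over all (start, length) pairs (vectorized per
    length with a cumulative GC count)."""
    import numpy as np

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    out: set[tuple[int, int]] = set()
    starts_all = np.arange(len(seq))
    for length in range(len_min, len_max + 1):
        starts = starts_all[: len(seq) - length + 1]
        ends = starts + length
        gc = 100.0 * (cum[ends] - cum[starts]) / length
        keep = (
            (starts - orf_start > margin)
            & (orf_end - ends > margin)
            & (gc >= gc_min)
            & (gc <= gc_max)
        )
        for s in starts[keep]:
            out.add((int(s), int(s) + length))
    return out
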