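"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is a direct, slow re-statement of the quantity under test
(textbook DP, exact combinatorics, naive scans) and shares no code with
the implementation paths it checks.
"""

import math

NEG = -(10 ** 9)


def brute_affine_score(query: str, window: str, match=2, mismatch=-4,
                       gap_open=-6, gap_extend=-1) -> int:
    """Exhaustive glocal affine-gap DP: query aligned end-to-end, free
    start/end in the window; first gap base costs open+extend."""
    L, W = len(query), len(window)
    M = [[NEG] * (W + 1) for _ in range(L + 1)]
    X = [[NEG] * (W + 1) for _ in range(L + 1)]
    Y = [[NEG] * (W + 1) for _ in range(L + 1)]
    for j in range(W + 1):
        M[0][j] = 0
    for i in range(1, L + 1):
        for j in range(W + 1):
            X[i][j] = max(max(M[i - 1][j], Y[i - 1][j]) + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend)
            if j > 0:
                s = match if query[i - 1] == window[j - 1] else mismatch
                M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                                  Y[i - 1][j - 1])
                Y[i][j] = max(max(M[i][j - 1], X[i][j - 1])
                              + gap_open + gap_extend,
                              Y[i][j - 1] + gap_extend)
    return max(max(M[L][j], X[L][j]) for j in range(W + 1))


def fisher_tail_p(alt_dp: int, total_dp: int, expected: int) -> float:
    """One-sided (greater) Fisher p for [[alt, N-alt], [E, N-E]] by
    summing the hypergeometric tail with exact integer combinatorics."""
    n1 = total_dp          # row 1 total
    n2 = total_dp          # row 2 total
    k = alt_dp + expected  # first-column total
    denom = math.comb(n1 + n2, k)
    p = 0
    for a in range(alt_dp, min(k, n1) + 1):
        b = k - a
        if 0 <= b <= n2:
            p += math.comb(n1, a) * math.comb(n2, b)
    return p / denom


def brute_offtarget_scan(seq: str, spacer: str, exclude=None):
    """Naive double-strand mismatch scan; returns ({(pos, strand): mm},
    genome-wide minimum)."""
    comp = str.maketrans("ACGT", "TGCA")
    best = len(spacer)
    frames = {}
    for strand in "+-":
        probe = spacer if strand == "+" else spacer.translate(comp)[::-1]
        for i in range(len(seq) - len(spacer) + 1):
            if exclude == (i + 1, strand):
                continue
            mm = sum(a != b for a, b in zip(seq[i:i + len(spacer)], probe))
            frames[(i + 1, strand)] = mm
            best = min(best, mm)
    return frames, best


def implied_haplotype(aln, genome) -> str:
    """Alternate sequence implied by an alignment over its reference
    span (M takes read bases, D skips reference, I adds read bases)."""
    out = []
    q = 0
    r = aln.pos
    for op, l in aln.cigar:
        if op == "S":
            q += l
        elif op == "M":
            out.append(aln.seq[q:q + l])
            q += l
            r += l
        elif op == "I":
            out.append(aln.seq[q:q + l])
            q += l
        elif op == "D":
            r += l
    return "".join(out)
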