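"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(per-position scans, exhaustive enumeration, direct series summation) and
deliberately shares no code with the implementation paths it checks.
"""

import math
from typing import Dict, List, Tuple


def scan_counts(seq: str) -> Tuple[int, int, int, int]:
    """(length, n_c, n_g, n_cpg) by a per-position scan, N excluded."""
    s = seq.upper()
    length = n_c = n_g = n_cpg = 0
    for i, ch in enumerate(s):
        if ch in "ACGT":
            length += 1
        if ch == "C":
            n_c += 1
            if i + 1 < len(s) and s[i + 1] == "G":
                n_cpg += 1
        elif ch == "G":
            n_g += 1
    return length, n_c, n_g, n_cpg


def scan_gc_oe(seq: str) -> Tuple[float, float]:
    length, n_c, n_g, n_cpg = scan_counts(seq)
    gc = (n_c + n_g) / length if length else 0.0
    oe = n_cpg * length / (n_c * n_g) if n_c * n_g else 0.0
    return gc, oe


def poisson_upper_tail(k: int, lam: float, terms: int = 400) -> float:
    """P(X >= k) by direct series summation of the complement."""
    if k <= 0:
        return 1.0
    # sum P(X = j) for j < k, in extended precision via log terms
    total = 0.0
    log_term = -lam  # log P(X=0)
    for j in range(k):
        total += math.exp(log_term)
        log_term += math.log(lam) - math.log(j + 1)
    return max(0.0, 1.0 - total)


def hypergeom_upper_tail(n: int, total: int, x: int, y: int) -> float:
    """P(X >= n) for X ~ Hypergeom(population=total, successes=x,
    draws=y), by explicit combinatorial enumeration."""
    denom = math.comb(total, y)
    s = 0
    for k in range(n, min(x, y) + 1):
        if y - k <= total - x:
            s += math.comb(x, k) * math.comb(total - x, y - k)
    return s / denom


def fisher_greater(table) -> float:
    """One-sided Fisher p for [[a,b],[c,d]] via the hypergeometric tail."""
    (a, b), (c, d) = table
    return hypergeom_upper_tail(a, a + b + c + d, a + b, a + c)


def bh_step_up(ps: List[float]) -> List[float]:
    """Textbook Benjamini-Hochberg step-up recomputation."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, ps[i] * m / rank)
        q[i] = prev
    return q


def brute_force_cgis(seq: str, min_gc: float, min_oe: float,
                     min_length: int, window: int,
                     step: int = 1) -> List[Tuple[int, int]]:
    """All-substring CGI oracle: collect every qualifying window's bases
    into a set, extract maximal runs, keep runs >= min_length whose
    whole-run composition also passes both thresholds."""
    n = len(seq)
    covered = set()
    for s in range(0, n - window + 1, step):
        gc, oe = scan_gc_oe(seq[s:s + window])
        length, *_ = scan_counts(seq[s:s + window])
        if length and gc >= min_gc and oe >= min_oe:
            covered.update(range(s, s + window))
    islands = []
    pos = sorted(covered)
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] == pos[j] + 1:
            j += 1
        s0, e0 = pos[i], pos[j] + 1
        if e0 - s0 >= min_length:
            gc, oe = scan_gc_oe(seq[s0:e0])
            if gc >= min_gc and oe >= min_oe:
                islands.append((s0, e0))
        i = j + 1
    return islands


def footprint_array(intervals, chrom: str, length: int):
    """Boolean per-base footprint of a collection of intervals."""
    arr = [False] * length
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        for p in range(max(0, iv.start), min(length, iv.end)):
            arr[p] = True
    return arr


def per_base_window_sum(track, chrom: str, start: int, end: int) -> float:
    """Signal area over a window by explicit per-base summation."""
    total = 0.0
    for p in range(max(0, start), min(track.chrom_sizes[chrom], end)):
        total += float(track.values(chrom, p, p + 1)[0])
    return total


def brute_force_cgis_prefix(seq: str, min_gc: float, min_oe: float,
                            min_length: int, window: int) -> List[Tuple[int, int]]:
    """Pure-python prefix-sum variant of the CGI oracle (same semantics as
    brute_force_cgis, fast enough for many 10-kb sequences)."""
    s = seq.upper()
    n = len(s)
    pa = [0] * (n + 1)  # ACGT
    pc = [0] * (n + 1)
    pg = [0] * (n + 1)
    pd = [0] * (n + 1)  # CpG starts
    for i, ch in enumerate(s):
        pa[i + 1] = pa[i] + (ch in "ACGT")
        pc[i + 1] = pc[i] + (ch == "C")
        pg[i + 1] = pg[i] + (ch == "G")
        pd[i + 1] = pd[i] + (ch == "C" and i + 1 < n and s[i + 1] == "G")
    covered = bytearray(n)
    one = b"\x01" * window
    for st in range(0, n - window + 1):
        length = pa[st + window] - pa[st]
        if not length:
            continue
        n_c = pc[st + window] - pc[st]
        n_g = pg[st + window] - pg[st]
        n_cpg = pd[st + window - 1] - pd[st]
        gc = (n_c + n_g) / length
        oe = n_cpg * length / (n_c * n_g) if n_c * n_g else 0.0
        if gc >= min_gc and oe >= min_oe:
            covered[st:st + window] = one
    islands = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            if j - i >= min_length:
                gc, oe = scan_gc_oe(s[i:j])
                if gc >= min_gc and oe >= min_oe:
                    islands.append((i, j))
            i = j
        else:
            i += 1
    return islands
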