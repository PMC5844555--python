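"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written in a different style from the package —
string searches and explicit enumeration instead of register arithmetic,
pure-python medians instead of numpy — so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import statistics

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in s[::-1])


def oracle_canonical(mir: str, utr: str) -> set[tuple[str, int, int]]:
    """Find canonical sites by literal string search for the seed target.

    The seed-target hexamer sits at 0-based window [i, i+5]; the base 5' of
    it (index i−1) pairs miRNA nt 8 and the base 3' (index i+6) is the A1
    position.  Coordinates returned 1-based inclusive.
    """
    seed_target = rc(mir[1:7])
    out = set()
    for i in range(len(utr) - 5):  # 0-based window start; 1-based = i+1
        if utr[i : i + 6] != seed_target:
            continue
        m8 = i > 0 and utr[i - 1] == COMP[mir[7]]
        a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if m8 and a1:
            out.add(("8mer", i, i + 7))
        elif m8:
            out.add(("7mer-m8", i, i + 6))
        elif a1:
            out.add(("7mer-A1", i + 1, i + 7))
        else:
            out.add(("6mer", i + 1, i + 6))
    return out


def oracle_offset6(mir: str, utr: str) -> set[tuple[str, int, int]]:
    pattern = rc(mir[2:8])  # targets miRNA nt 3–8
    out = set()
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != pattern:
            continue
        nt2_pairs = i + 6 < len(utr) and utr[i + 6] == COMP[mir[1]]
        if not nt2_pairs:
            out.add(("offset6", i + 1, i + 6))
    return out


def oracle_mismatch(mir: str, utr: str) -> set[tuple[str, int, int, int]]:
    """(class, start, end, mismatch_pos) for single-mismatch seed windows."""
    perfect = rc(mir[1:7])
    out = set()
    for i in range(len(utr) - 5):
        window = utr[i : i + 6]
        diff = [j for j in range(6) if window[j] != perfect[j]]
        if len(diff) != 1:
            continue
        j = diff[0]
        k = 7 - j  # window position j targets miRNA seed position 7 − j
        mb, tb = mir[k - 1], window[j]
        cls = "gu_wobble" if {mb, tb} == {"G", "U"} else "seed_mismatch"
        out.add((cls, i + 1, i + 6, k))
    return out


def oracle_gbulge(mir: str, utr: str) -> set[tuple[str, int, int]]:
    perfect = rc(mir[1:7])
    out = set()
    for i in range(len(utr) - 6):
        window = utr[i : i + 7]
        # delete each base in turn; a valid deletion removes a G sitting
        # between the bases that pair miRNA nt 6 and nt 5 (window index 2)
        if window[2] == "G" and window[:2] + window[3:] == perfect:
            out.add(("gbulge", i + 1, i + 7))
    return out


def oracle_centered(mir: str, utr: str) -> set[tuple[str, int, int]]:
    if len(mir) < 15:
        return set()
    out = set()
    for lo, hi in ((4, 14), (5, 15)):
        pattern = rc(mir[lo - 1 : hi])
        for i in range(len(utr) - len(pattern) + 1):
            if utr[i : i + len(pattern)] != pattern:
                continue

            # target base pairing miRNA position k sits at 0-based i + hi − k
            def pairs(k):
                idx = i + hi - k
                return (1 <= k <= len(mir) and 0 <= idx < len(utr)
                        and utr[idx] == COMP[mir[k - 1]])

            if all(pairs(kk) for kk in range(2, 8)):  # canonical register
                continue
            klo, khi = lo, hi
            while pairs(klo - 1):
                klo -= 1
            while pairs(khi + 1):
                khi += 1
            out.add(("centered", i + hi - khi + 1, i + hi - klo + 1))
    return out


def oracle_supp3p(mir: str, utr: str, register: int, lo=13, hi=16, need=3) -> bool:
    run = best = 0
    for k in range(lo, hi + 1):
        pos = register - k + 1
        ok = 1 <= pos <= len(utr) and k <= len(mir) and utr[pos - 1] == COMP[mir[k - 1]]
        run = run + 1 if ok else 0
        best = max(best, run)
    return best >= need


def oracle_median_polish(grid, tol=1e-9, max_iter=100):
    """Pure-python row/column median sweeps on a list-of-lists grid."""
    import math

    r = [row[:] for row in grid]
    nrow, ncol = len(r), len(r[0])
    for _ in range(max_iter):
        biggest = 0.0
        for i in range(nrow):
            vals = [x for x in r[i] if not math.isnan(x)]
            m = statistics.median(vals)
            biggest = max(biggest, abs(m))
            r[i] = [x - m for x in r[i]]
        for j in range(ncol):
            vals = [r[i][j] for i in range(nrow) if not math.isnan(r[i][j])]
            m = statistics.median(vals)
            biggest = max(biggest, abs(m))
            for i in range(nrow):
                r[i][j] -= m
        if biggest < tol:
            break
    return r


def oracle_auc(positives, negatives) -> float:
    """Ordered-pair probability that a positive scores below a negative."""
    wins = 0.0
    for p, n in itertools.product(positives, negatives):
        if p < n:
            wins += 1.0
        elif p == n:
            wins += 0.5
    return wins / (len(positives) * len(negatives))


def oracle_dplus(a, b) -> float:
    """sup_x F_a(x) − F_b(x) by direct ECDF evaluation at every point."""
    best = 0.0
    for x in list(a) + list(b):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, fa - fb)
    return best


def oracle_bh(pvals):
    """Step-up Benjamini–Hochberg by the textbook recipe."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def oracle_average_linkage(points: dict[str, list[float]]):
    """Naive agglomeration under average linkage / Euclidean distance.

    Returns the merge order as a list of frozensets (the clusters created).
    """
    import math

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    clusters: list[frozenset[str]] = [frozenset([k]) for k in sorted(points)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = statistics.mean(
                    dist(points[a], points[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges
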