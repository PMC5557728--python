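"""Independent pure-Python oracles used to validate satlib's implementations.

Everything here is deliberately written from first principles (naive dynamic
programming, exhaustive enumeration) and shares no code with the package.
Only use at tiny problem sizes.
"""
from __future__ import annotations

import itertools
from math import inf

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def local_align_identity(query: str, target: str, match=1, mismatch=-1,
                         gap_open=-2, gap_extend=-1):
    """Affine-gap Smith-Waterman with traceback.

    Returns (identity, columns, score) of the best local alignment, where
    identity = matches / alignment columns (gap columns count, N never
    matches). gap_open is the score of the first gap position.
    """
    n, m = len(query), len(target)
    NEG = -inf
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (query consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target consumed)
    best = (0.0, 0, 0)  # score, i, j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (query[i - 1] == target[j - 1] and query[i - 1] in "ACGT") \
                else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            local_best = max(M[i][j], X[i][j], Y[i][j])
            if local_best > best[0]:
                best = (local_best, i, j)
    score, i, j = best
    if score <= 0:
        return 0.0, 0, 0.0
    # traceback from the best cell through whichever matrix holds the max
    state = max((("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])),
                key=lambda kv: kv[1])[0]
    matches = columns = 0
    while i > 0 and j > 0:
        if state == "M":
            cur = M[i][j]
            s = match if (query[i - 1] == target[j - 1] and query[i - 1] in "ACGT") \
                else mismatch
            columns += 1
            if s == match:
                matches += 1
            prevs = {"M": M[i - 1][j - 1], "X": X[i - 1][j - 1],
                     "Y": Y[i - 1][j - 1], "0": 0.0}
            state = next(k for k in ("0", "M", "X", "Y")
                         if abs(prevs[k] - (cur - s)) < 1e-9)
            i -= 1
            j -= 1
            if state == "0":
                break
        elif state == "X":
            cur = X[i][j]
            columns += 1
            state = "M" if abs(M[i - 1][j] + gap_open - cur) < 1e-9 else "X"
            i -= 1
        else:
            cur = Y[i][j]
            columns += 1
            state = "M" if abs(M[i][j - 1] + gap_open - cur) < 1e-9 else "Y"
            j -= 1
    return matches / columns if columns else 0.0, columns, score


def brute_force_pi(rows: list[str], counts: list[int],
                   indel_policy: str = "gap_as_event") -> float:
    """pi by literal expansion over all C(n,2) sequence pairs."""
    expanded = []
    for row, c in zip(rows, counts):
        expanded.extend([row] * c)
    pairs = list(itertools.combinations(range(len(expanded)), 2))
    total = 0.0
    for i, j in pairs:
        a, b = expanded[i], expanded[j]
        if indel_policy == "complete_deletion":
            cols = [(x, y) for x, y in zip(a, b)
                    if "-" not in (x, y)]
            # complete deletion removes columns gapped in ANY row
            keep = [k for k in range(len(a))
                    if all(r[k] != "-" for r in rows)]
            cols = [(a[k], b[k]) for k in keep]
            valid = [(x, y) for x, y in cols if x in "ACGT" and y in "ACGT"]
            d = sum(x != y for x, y in valid)
            L = len(valid)
        else:
            valid = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
            d = sum(x != y for x, y in valid)
            events = 0
            for which in (0, 1):
                run = False
                for x, y in zip(a, b):
                    only = (x == "-" and y != "-") if which == 0 \
                        else (y == "-" and x != "-")
                    if only and not run:
                        events += 1
                    run = only
            d += events
            L = len(valid) + events
        total += d / L
    return total / len(pairs)


def pair_distance(a: str, b: str) -> int:
    """Mutational distance over two aligned rows: substitutions + indel events."""
    d = sum(x != y and x in "ACGT" and y in "ACGT" for x, y in zip(a, b))
    for which in (0, 1):
        run = False
        for x, y in zip(a, b):
            only = (x == "-" and y != "-") if which == 0 else (y == "-" and x != "-")
            if only and not run:
                d += 1
            run = only
    return d


def min_spanning_tree_weight(dist) -> float:
    """Exhaustive minimum over all spanning trees (n <= 7)."""
    n = len(dist)
    if n == 1:
        return 0.0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(dist[i][j] for i, j in subset))
    return best


def scan_pcr_products(template: str, fwd: str, rev: str, max_mm: int,
                      lo: int, hi: int):
    """Enumerate primer site pairs by brute scanning under IUPAC semantics."""
    def sites(t, primer):
        out = []
        for i in range(len(t) - len(primer) + 1):
            mm = sum(t[i + k] not in IUPAC_SETS[primer[k]]
                     for k in range(len(primer)))
            if mm <= max_mm:
                out.append(i)
        return out

    fwd_sites = sites(template, fwd.upper())
    rc_rev = revcomp_iupac(rev.upper())
    rev_sites = sites(template, rc_rev)
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            length = j + len(rev) - i
            if lo <= length <= hi:
                products.append((i, j + len(rev), length))
    return sorted(products)


_IUPAC_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
               "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
               "D": "H", "H": "D", "N": "N"}


def revcomp_iupac(seq: str) -> str:
    return "".join(_IUPAC_COMP[c] for c in reversed(seq))


def best_rotations(monomer: str, consensus: str) -> tuple[int, list[str]]:
    """(min edit distance, all rotation strings achieving it)."""
    L = len(monomer)
    doubled = monomer + monomer
    dists = [(edit_distance(doubled[k:k + L], consensus), doubled[k:k + L])
             for k in range(L)]
    dmin = min(d for d, _ in dists)
    return dmin, sorted({r for d, r in dists if d == dmin})


def best_merge_overlap(m1: str, m2_rc: str, min_overlap: int):
    """Enumerate every candidate overlap; return (mismatch_frac, overlap, mism)."""
    best = None
    for o in range(min_overlap, min(len(m1), len(m2_rc)) + 1):
        sa, sb = m1[-o:], m2_rc[:o]
        mm = sum(x != y or x == "N" or y == "N" for x, y in zip(sa, sb))
        key = (mm / o, -o)
        if best is None or key < (best[0], -best[1]):
            best = (mm / o, o, mm)
    return best
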