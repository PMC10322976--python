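"""Independent brute-force oracles used to validate the optimized implementations.

These deliberately re-derive results from first principles (direct extension at
every start position, full-text string search, random additive trees) and must
stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np

_ACGT = set("ACGT")

DEFAULT_MIN = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}


def _primitive(motif: str) -> bool:
    k = len(motif)
    return not any(
        k % p == 0 and motif == motif[:p] * (k // p) for p in range(1, k)
    )


def brute_force_perfect_ssrs(seq: str, min_repeats: dict | None = None) -> set:
    """Every maximal perfect SSR by direct extension at every start position.

    Returns a set of (start, end, motif, repeats) with 1-based inclusive
    coordinates and tracts truncated to whole motif copies.
    """
    minrep = min_repeats or DEFAULT_MIN
    n = len(seq)
    out = set()
    for k in range(1, 7):
        for a in range(n - k):
            motif = seq[a : a + k]
            if not set(motif) <= _ACGT:
                continue
            # left-maximality: extending one base left must break the period
            if a >= 1 and seq[a - 1] in _ACGT and seq[a - 1] == seq[a - 1 + k]:
                continue
            b = a + k
            while b < n and seq[b] in _ACGT and seq[b] == seq[b - k]:
                b += 1
            reps = (b - a) // k
            if reps >= minrep[k] and _primitive(motif):
                out.add((a + 1, a + k * reps, motif, reps))
    return out


def naive_epcr(
    forward: str,
    reverse: str,
    seq: str,
    amplicon_min: int = 100,
    amplicon_max: int = 1000,
) -> set:
    """Exact-match amplicons on one sequence by exhaustive full-text search.

    Returns a set of (start, end) 1-based inclusive 5'-to-5' spans.
    """
    comp = str.maketrans("ACGTN", "TGCAN")

    def rc(s: str) -> str:
        return s.translate(comp)[::-1]

    def all_hits(needle: str) -> list[int]:
        hits, i = [], seq.find(needle)
        while i >= 0:
            hits.append(i)
            i = seq.find(needle, i + 1)
        return hits

    out = set()
    for left, right in ((forward, reverse), (reverse, forward)):
        left_hits = all_hits(left)
        right_hits = all_hits(rc(right))
        for i in left_hits:
            for j in right_hits:
                end = j + len(right) - 1
                if end > i and amplicon_min <= end - i + 1 <= amplicon_max:
                    out.add((i + 1, end + 1))
    return out


def random_additive_distances(
    rng: np.random.Generator, n_leaves: int = 10
) -> tuple[list[str], np.ndarray]:
    """Pairwise path-length distances of a random binary tree with positive
    branch lengths (an additive metric, which NJ must recover exactly)."""
    ids = [f"s{i}" for i in range(n_leaves)]
    index = {x: i for i, x in enumerate(ids)}
    D = np.zeros((n_leaves, n_leaves))
    clusters = [{x: 0.0} for x in ids]  # leaf -> distance to cluster root
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        bi, bj = rng.uniform(0.5, 2.0, 2)
        a = {l: d + bi for l, d in clusters[i].items()}
        b = {l: d + bj for l, d in clusters[j].items()}
        for la, da in a.items():
            for lb, db in b.items():
                D[index[la], index[lb]] = D[index[lb], index[la]] = da + db
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [{**a, **b}]
    edge = rng.uniform(0.5, 2.0)
    a, b = clusters
    for la, da in a.items():
        for lb, db in b.items():
            D[index[la], index[lb]] = D[index[lb], index[la]] = da + edge + db
    return ids, D


def exhaustive_primer_pairs(seq: str, tract_start: int, tract_end: int, tm_fn, gc_fn):
    """All legal primer pairs by direct enumeration with the declared penalty.

    ``tract_start``/``tract_end`` are 1-based inclusive; returns a list of
    (penalty, forward_start0, forward_seq, reverse_start0, reverse_seq,
    product) sorted by (penalty, forward_start0, forward_seq).
    """
    comp = str.maketrans("ACGT", "TGCA")
    ts0, te0 = tract_start - 1, tract_end - 1
    fwd, rev = [], []
    for L in (18, 19, 20):
        for a in range(max(0, ts0 - 400), ts0 - L + 1):
            w = seq[a : a + L]
            if set(w) <= _ACGT and 40 <= gc_fn(w) <= 70 and 52 <= tm_fn(w) <= 60:
                fwd.append((a, w))
        for a in range(te0 + 1, min(len(seq), te0 + 1 + 400) - L + 1):
            w = seq[a : a + L].translate(comp)[::-1]
            if set(w) <= _ACGT and 40 <= gc_fn(w) <= 70 and 52 <= tm_fn(w) <= 60:
                rev.append((a, w))
    pairs = []
    for fa, fw in fwd:
        for ra, rw in rev:
            product = (ra + len(rw) - 1) - fa + 1
            if 100 <= product <= 400:
                pen = (
                    abs(tm_fn(fw) - 55) + abs(tm_fn(rw) - 55)
                    + abs(len(fw) - 19) + abs(len(rw) - 19)
                    + abs(product - 250) / 100
                )
                pairs.append((pen, fa, fw, ra, rw, product))
    return sorted(pairs, key=lambda t: (t[0], t[1], t[2]))
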