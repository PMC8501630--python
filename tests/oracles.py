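"""Independent brute-force oracles used to cross-check the implementation.

Everything here works by per-base expansion on small genomes (<= 1e4 bases)
or by exact enumeration, deliberately avoiding the code paths under test.
"""

from __future__ import annotations

import math

import numpy as np


def expand_per_base(segments):
    """Expand (chrom, start, end, a, b) tuples to per-base parallel lists.

    Returns (chroms, positions, a, b, c) sorted by (chrom, position).
    Intended only for tiny synthetic genomes.
    """
    rows = []
    for chrom, start, end, a, b in segments:
        for pos in range(start, end + 1):
            rows.append((chrom, pos, a, b, a + b))
    rows.sort(key=lambda r: (r[0], r[1]))
    chroms = [r[0] for r in rows]
    positions = [r[1] for r in rows]
    a = np.array([r[2] for r in rows], dtype=float)
    b = np.array([r[3] for r in rows], dtype=float)
    c = np.array([r[4] for r in rows], dtype=float)
    return chroms, positions, a, b, c


def per_base_median(values) -> float:
    """Lower median: smallest v whose cumulative count reaches half."""
    s = sorted(values)
    return float(s[math.ceil(len(s) / 2) - 1])


def per_base_scores(segments, ploidy: float, w0: float) -> dict:
    """All eight complexity scores from a per-base expansion."""
    chroms, _, a, b, c = expand_per_base(segments)
    W = len(c)
    m = per_base_median(c)

    scores = {
        "var": float(np.mean(np.abs(c - m))),
        "dev": float(np.mean(np.abs(c - ploidy))),
        "gain": float(np.mean(np.maximum(0.0, c - ploidy))),
        "loss": float(np.mean(np.maximum(0.0, ploidy - c))),
        "loh": float(np.mean(np.where((b == 0) & (c >= 1), a - b, 0.0))),
        "asym": float(np.mean(np.where(b >= 1, a - b, 0.0))),
    }

    # runs of constant (a, b) within one chromosome (base-level scan)
    runs = []  # (chrom, length, total)
    for i in range(W):
        key = (chroms[i], a[i], b[i])
        if runs and runs[-1][0] == key[0] and runs[-1][2] == (a[i], b[i]):
            runs[-1][1] += 1
        else:
            runs.append([chroms[i], 1, (a[i], b[i])])

    j2 = 0.0
    for r1, r2 in zip(runs, runs[1:]):
        if r1[0] != r2[0]:
            continue
        c1, c2 = sum(r1[2]), sum(r2[2])
        j2 += abs(c2 - c1) * min(r1[1], r2[1], w0)
    scores["steep"] = j2 / W

    j3 = 0.0
    for prev, cur, nxt in zip(runs, runs[1:], runs[2:]):
        if not (prev[0] == cur[0] == nxt[0]):
            continue
        cp, cc, cn = sum(prev[2]), sum(cur[2]), sum(nxt[2])
        if cc < min(cp, cn):
            e = min(cp, cn) - cc
        elif cc > max(cp, cn):
            e = cc - max(cp, cn)
        else:
            continue
        j3 += e * min(cur[1], w0)
    scores["curv"] = j3 / W
    return scores


def hypergeom_tail(overlap: int, set_size: int, cis_count: int, universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, cis_count)."""
    total = 0.0
    for k in range(overlap, min(set_size, cis_count) + 1):
        total += (
            math.comb(set_size, k)
            * math.comb(universe - set_size, cis_count - k)
            / math.comb(universe, cis_count)
        )
    return min(1.0, total)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up by direct arithmetic."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def random_small_profile(rng: np.random.Generator, max_bases: int = 10_000):
    """Random tiny allele-specific genome as (chrom, start, end, a, b) tuples.

    Two chromosomes, abutting integer segments, occasional gaps.
    """
    segments = []
    for chrom in ("1", "2"):
        genome_len = int(rng.integers(200, max_bases // 2))
        n_breaks = int(rng.integers(1, 12))
        cuts = sorted(set(rng.integers(2, genome_len, size=n_breaks).tolist()))
        bounds = [1] + cuts + [genome_len]
        pos = 0
        while pos < len(bounds) - 1:
            start, end = bounds[pos], bounds[pos + 1] - (0 if pos == len(bounds) - 2 else 1)
            if rng.random() < 0.1:  # coverage gap
                pos += 1
                continue
            a = int(rng.integers(0, 5))
            b = int(rng.integers(0, a + 1))
            segments.append((chrom, start, end, a, b))
            pos += 1
    if not segments:
        segments.append(("1", 1, 100, 1, 1))
    return segments
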