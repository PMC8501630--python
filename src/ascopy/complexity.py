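"""Eight-index genomic-complexity scoring of allele-specific profiles.

A copy number profile over a genomic region R is compressed into eight
non-negative, length-normalised scores.  With clipped segments i = 1..n in
R of length L_i, total copies c_i and allele copies a_i >= b_i, region
width W = sum(L_i), region median m (length-weighted lower median of c) and
genome ploidy P:

=========  =========================================================
var   J1   (1/W) sum_i L_i * |c_i - m|
steep J2   (1/W) sum over adjacent pairs |c_{j+1} - c_j| * min(L_j, L_{j+1}, w0)
curv  J3   (1/W) sum over interior segments e_j * min(L_j, w0), where e_j
           is the depth/height of a strict local minimum/maximum of c
dev   J4   (1/W) sum_i L_i * |c_i - P|
gain  J5   (1/W) sum_i L_i * max(0, c_i - P)
loss  J6   (1/W) sum_i L_i * max(0, P - c_i)
loh   J7   (1/W) sum over segments with b_i = 0, c_i >= 1 of L_i * (a_i - b_i)
asym  J8   (1/W) sum over segments with b_i >= 1 of L_i * (a_i - b_i)
=========  =========================================================

var measures local variation around the regional median; steep and curv
capture focal complex events (narrow shifts, and shifts that oscillate);
dev/gain/loss weigh deviation from the genome ploidy by magnitude and
width; loh counts allelic skewness where one allele is completely lost,
asym skewness where both alleles are retained.  The first six scores use
total copies only, the last two the allele-specific values.  The width cap
w0 (default 3 Mb) makes narrow shifts count fully while wide flanks
contribute at most w0.  Scores decompose as J4 = J5 + J6.

Adjacent segments with identical (a, b) are merged before scoring so that
breakpoint terms reflect true copy transitions; chromosome boundaries never
form breakpoints.  Homozygous deletions (c = 0) contribute to loss, not to
loh (nothing is retained).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout, SampleProfile
from .ploidy_calls import resolve_ploidy, weighted_median

logger = logging.getLogger("ascopy")

__all__ = [
    "SCORE_NAMES",
    "ScoreConfig",
    "ComplexityScores",
    "score_region",
    "score_genome_wide",
    "score_arm_wise",
    "scores_to_long",
    "scores_to_wide",
    "write_scores",
]

SCORE_NAMES = ("var", "steep", "curv", "dev", "gain", "loss", "loh", "asym")


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring parameters: width cap w0 (bp) and region mode."""

    w0: float = 3_000_000.0
    mode: str = "genome"  # "genome" or "arm"

    def __post_init__(self) -> None:
        if not self.w0 > 0:
            raise ValueError("w0 must be > 0")


@dataclass(frozen=True)
class ComplexityScores:
    """The eight complexity indices for one (sample, region) pair."""

    sample: str
    region: str
    var: float
    steep: float
    curv: float
    dev: float
    gain: float
    loss: float
    loh: float
    asym: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SCORE_NAMES}

    @property
    def missing(self) -> bool:
        return math.isnan(self.var)


def _clip_segments(
    profile: SampleProfile, intervals: Sequence[tuple[str, int, int]] | None
) -> list[tuple[str, int, int, int, int]]:
    """Clip profile segments to the interval set; returns (chrom, L, a, b, c)."""
    out: list[tuple[str, int, int, int, int]] = []
    if intervals is None:
        for s in profile.segments:
            out.append((s.chrom, s.length, s.a, s.b, s.c))
        return out
    for s in profile.segments:
        for chrom, lo, hi in intervals:
            if s.chrom != chrom:
                continue
            start = max(s.start, lo)
            end = min(s.end, hi)
            if end >= start:
                out.append((s.chrom, end - start + 1, s.a, s.b, s.c))
    return out


def _merge_equal(clipped: list[tuple[str, int, int, int, int]]):
    """Merge consecutive same-chromosome pieces with identical (a, b)."""
    merged: list[list] = []
    for chrom, L, a, b, c in clipped:
        if merged and merged[-1][0] == chrom and merged[-1][2] == a and merged[-1][3] == b:
            merged[-1][1] += L
        else:
            merged.append([chrom, L, a, b, c])
    return merged


def score_region(
    profile: SampleProfile,
    region: Sequence[tuple[str, int, int]] | None,
    ploidy: float,
    config: ScoreConfig = ScoreConfig(),
    region_id: str = "region",
) -> ComplexityScores:
    """Compress the profile over *region* into the eight complexity scores.

    *region* is a set of (chrom, start, end) intervals (1-based inclusive),
    or ``None`` for the whole profiled genome.  A region with zero covered
    length yields all-NaN (missing) scores, not zeros.
    """
    segs = _merge_equal(_clip_segments(profile, region))
    if not segs:
        logger.debug("sample %s region %s: no covered bases, scores missing",
                      profile.sample, region_id)
        nan = float("nan")
        return ComplexityScores(profile.sample, region_id, *([nan] * 8))

    chroms = np.array([s[0] for s in segs])
    L = np.array([s[1] for s in segs], dtype=float)
    a = np.array([s[2] for s in segs], dtype=float)
    b = np.array([s[3] for s in segs], dtype=float)
    c = np.array([s[4] for s in segs], dtype=float)
    W = L.sum()
    m = weighted_median(c, L)
    w0 = float(config.w0)

    j1 = float(np.sum(L * np.abs(c - m)) / W)
    j4 = float(np.sum(L * np.abs(c - ploidy)) / W)
    j5 = float(np.sum(L * np.maximum(0.0, c - ploidy)) / W)
    j6 = float(np.sum(L * np.maximum(0.0, ploidy - c)) / W)
    j7 = float(np.sum(L[(b == 0) & (c >= 1)] * (a - b)[(b == 0) & (c >= 1)]) / W)
    j8 = float(np.sum(L[b >= 1] * (a - b)[b >= 1]) / W)

    # breakpoint terms: adjacent pairs within one chromosome
    j2 = 0.0
    for j in range(len(segs) - 1):
        if chroms[j] == chroms[j + 1]:
            j2 += abs(c[j + 1] - c[j]) * min(L[j], L[j + 1], w0)
    j2 = float(j2 / W)

    # oscillation terms: strict local extrema among interior segments
    j3 = 0.0
    for j in range(1, len(segs) - 1):
        if chroms[j - 1] != chroms[j] or chroms[j] != chroms[j + 1]:
            continue
        lo_nb = min(c[j - 1], c[j + 1])
        hi_nb = max(c[j - 1], c[j + 1])
        if c[j] < lo_nb:
            e = lo_nb - c[j]
        elif c[j] > hi_nb:
            e = c[j] - hi_nb
        else:
            continue
        j3 += e * min(L[j], w0)
    j3 = float(j3 / W)

    return ComplexityScores(profile.sample, region_id, j1, j2, j3, j4, j5, j6, j7, j8)


def score_genome_wide(
    profile: SampleProfile, config: ScoreConfig = ScoreConfig()
) -> ComplexityScores:
    """The eight scores over the whole profiled genome."""
    ploidy = resolve_ploidy(profile)
    return score_region(profile, None, ploidy, config, region_id="genome")


def score_arm_wise(
    profile: SampleProfile,
    layout: GenomeLayout,
    config: ScoreConfig = ScoreConfig(mode="arm"),
) -> list[ComplexityScores]:
    """One ComplexityScores per chromosome arm (missing for uncovered arms).

    With the default 43-arm layout this yields 8 x 43 = 344 score values
    per tumor.  Ploidy is the genome-wide value throughout.
    """
    ploidy = resolve_ploidy(profile)
    out = []
    for arm in layout.arms:
        out.append(
            score_region(
                profile, [(arm.chrom, arm.start, arm.end)], ploidy, config,
                region_id=arm.name,
            )
        )
    return out


def scores_to_long(scores: Iterable[ComplexityScores]) -> pd.DataFrame:
    """Long format: one row per (sample, region) with the eight score columns."""
    rows = []
    for s in scores:
        rows.append({"sample": s.sample, "region": s.region, **s.as_dict()})
    return pd.DataFrame(rows, columns=["sample", "region", *SCORE_NAMES])


def scores_to_wide(scores: Iterable[ComplexityScores]) -> pd.DataFrame:
    """Wide format: index sample, one column per ``region.score``."""
    long = scores_to_long(scores)
    melted = long.melt(id_vars=["sample", "region"], var_name="score")
    melted["col"] = melted["region"] + "." + melted["score"]
    wide = melted.pivot(index="sample", columns="col", values="value")
    # keep deterministic column order: region blocks in input order
    order = []
    for region in long["region"].drop_duplicates():
        order.extend(f"{region}.{n}" for n in SCORE_NAMES)
    return wide[order]


def write_scores(scores: Iterable[ComplexityScores], path: str | Path, wide: bool = False) -> None:
    df = scores_to_wide(scores) if wide else scores_to_long(scores)
    df.to_csv(path, sep="\t", index=wide)
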