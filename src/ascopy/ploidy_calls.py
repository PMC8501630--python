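"""Tumor ploidy estimation and ploidy-relative aberration calling.

Ploidy is the length-weighted median total copy number across the genome:
the smallest total copy value v such that segments with c <= v cover at
least half of the profiled genome.  Segments are then called *gain* when
their total copy number exceeds ploidy (by more than a tolerance delta),
*loss* when below it, and *normal* otherwise.  With delta = 0 and a
non-integer ploidy the normal class is empty by construction; downstream
grouping steps that need a normal class use delta = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import SampleProfile, Segment

logger = logging.getLogger("ascopy")

__all__ = [
    "AberrationCall",
    "weighted_median",
    "compute_ploidy",
    "resolve_ploidy",
    "call_segment",
    "call_profile",
    "calls_to_frame",
    "write_calls",
]

GAIN, LOSS, NORMAL = "gain", "loss", "normal"


@dataclass(frozen=True)
class AberrationCall:
    """A gain/loss/normal label for one segment, relative to ploidy."""

    segment: Segment
    call: str  # gain | loss | normal
    delta: float


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: smallest v with cumulative weight >= total/2."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty sequence")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, w.sum() / 2.0))
    return float(v[idx])


def compute_ploidy(profile: SampleProfile) -> float:
    """Length-weighted median total copy number of the profile.

    If the profile carries a supplied (caller-estimated) ploidy, that value
    takes precedence and the computed median is logged for comparison.
    """
    if not profile.segments:
        raise ValueError(f"sample {profile.sample}: cannot compute ploidy of empty profile")
    med = weighted_median(
        [s.c for s in profile.segments], [s.length for s in profile.segments]
    )
    if profile.ploidy is not None:
        logger.debug(
            "sample %s: supplied ploidy %.3f takes precedence (weighted median %.3f)",
            profile.sample, profile.ploidy, med,
        )
        return float(profile.ploidy)
    return med


def resolve_ploidy(profile: SampleProfile) -> float:
    """Supplied ploidy if present, else the length-weighted median."""
    return compute_ploidy(profile)


def call_segment(segment: Segment, ploidy: float, delta: float = 0.0) -> AberrationCall:
    """Call one segment gain/loss/normal relative to *ploidy* with band *delta*."""
    if not ploidy > 0:
        raise ValueError("ploidy must be > 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if segment.c > ploidy + delta:
        label = GAIN
    elif segment.c < ploidy - delta:
        label = LOSS
    else:
        label = NORMAL
    return AberrationCall(segment, label, delta)


def call_profile(profile: SampleProfile, delta: float = 0.0) -> list[AberrationCall]:
    """Call every segment of a profile against its (resolved) ploidy."""
    ploidy = resolve_ploidy(profile)
    return [call_segment(s, ploidy, delta) for s in profile.segments]


def calls_to_frame(calls: Iterable[AberrationCall]) -> pd.DataFrame:
    rows = [
        (c.segment.sample, c.segment.chrom, c.segment.start, c.segment.end,
         c.segment.c, c.call, c.delta)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["sample", "chr", "start", "end", "c", "call", "delta"])


def write_calls(calls: Iterable[AberrationCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
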