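"""Cohort gain/loss frequency tracks and recurrent aberrant regions.

Breakpoints from all samples partition each chromosome into atomic
intervals.  Per interval, the gain (loss) frequency is the number of
samples whose gain (loss) call covers it divided by the number of samples
covering it at all — uncovered samples do not dilute the denominator, and
the per-interval n is reported.  Maximal runs of abutting atomic intervals
whose frequency reaches a fixed proportion p (default 0.30, compared
inclusively) form recurrent aberrant regions, which are then annotated with
overlapping genes and cytobands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneAnnotation, SampleProfile, _chrom_rank
from .ploidy_calls import GAIN, LOSS, AberrationCall

logger = logging.getLogger("ascopy")

__all__ = [
    "FrequencyTrack",
    "RecurrentRegion",
    "aberration_frequency",
    "recurrent_regions",
    "annotate_regions",
    "regions_to_frame",
    "write_regions",
    "plot_frequency",
    "proportion_as_percent",
    "locus_loh_summary",
]


@dataclass(frozen=True)
class FrequencyTrack:
    """Atomic-interval gain/loss frequencies across the cohort.

    ``data`` columns: chrom, start, end, n (covering samples),
    freq_gain, freq_loss.  Atomic intervals tile each chromosome's covered
    span without overlap.
    """

    data: pd.DataFrame

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class RecurrentRegion:
    """A maximal interval whose gain or loss frequency meets the threshold."""

    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    peak_frequency: float
    mean_frequency: float
    genes: list[str] = field(default_factory=list)
    cytobands: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def aberration_frequency(
    calls_by_sample: Mapping[str, Sequence[AberrationCall]]
) -> FrequencyTrack:
    """Build the per-interval gain/loss frequency track from per-sample calls."""
    if not calls_by_sample:
        raise ValueError("aberration_frequency requires at least one sample")

    # collect breakpoints per chromosome across all samples
    breaks: dict[str, set[int]] = {}
    for calls in calls_by_sample.values():
        for call in calls:
            s = call.segment
            breaks.setdefault(s.chrom, set()).update((s.start, s.end + 1))

    rows = []
    for chrom in sorted(breaks, key=_chrom_rank):
        pts = np.array(sorted(breaks[chrom]))
        starts, ends = pts[:-1], pts[1:] - 1
        n_cov = np.zeros(len(starts), dtype=int)
        n_gain = np.zeros(len(starts), dtype=int)
        n_loss = np.zeros(len(starts), dtype=int)
        for calls in calls_by_sample.values():
            for call in calls:
                s = call.segment
                if s.chrom != chrom:
                    continue
                i = np.searchsorted(starts, s.start)
                j = np.searchsorted(starts, s.end + 1)
                n_cov[i:j] += 1
                if call.call == GAIN:
                    n_gain[i:j] += 1
                elif call.call == LOSS:
                    n_loss[i:j] += 1
        keep = n_cov > 0
        for st, en, nc, ng, nl in zip(starts[keep], ends[keep], n_cov[keep],
                                      n_gain[keep], n_loss[keep]):
            rows.append((chrom, int(st), int(en), int(nc), ng / nc, nl / nc))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n", "freq_gain", "freq_loss"])
    return FrequencyTrack(df)


def recurrent_regions(track: FrequencyTrack, p: float = 0.30) -> list[RecurrentRegion]:
    """Maximal runs of abutting atomic intervals with frequency >= p, per direction."""
    if not (0 < p <= 1):
        raise ValueError("threshold p must be in (0, 1]")
    regions: list[RecurrentRegion] = []
    df = track.data
    for direction, col in ((GAIN, "freq_gain"), (LOSS, "freq_loss")):
        run: list[pd.Series] = []
        for _, row in df.iterrows():
            if row[col] >= p:
                if run and not (
                    run[-1]["chrom"] == row["chrom"] and run[-1]["end"] + 1 == row["start"]
                ):
                    regions.append(_close_run(run, direction, col))
                    run = []
                run.append(row)
            elif run:
                regions.append(_close_run(run, direction, col))
                run = []
        if run:
            regions.append(_close_run(run, direction, col))
    regions.sort(key=lambda r: (_chrom_rank(r.chrom), r.start, r.direction))
    return regions


def _close_run(run: list[pd.Series], direction: str, col: str) -> RecurrentRegion:
    freqs = np.array([r[col] for r in run])
    lengths = np.array([r["end"] - r["start"] + 1 for r in run], dtype=float)
    return RecurrentRegion(
        chrom=str(run[0]["chrom"]),
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        direction=direction,
        peak_frequency=float(freqs.max()),
        mean_frequency=float(np.average(freqs, weights=lengths)),
    )


def annotate_regions(
    regions: list[RecurrentRegion], genes: Sequence[GeneAnnotation]
) -> list[RecurrentRegion]:
    """Attach gene symbols and cytobands overlapping each region by >= 1 bp."""
    for region in regions:
        hits = [
            g for g in genes
            if g.chrom == region.chrom and g.start <= region.end and g.end >= region.start
        ]
        region.genes = [g.gene for g in hits]
        bands: list[str] = []
        for g in hits:
            if g.cytoband and g.cytoband not in bands:
                bands.append(g.cytoband)
        region.cytobands = bands
    return regions


def regions_to_frame(regions: Iterable[RecurrentRegion]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.start, r.end, r.direction, r.peak_frequency, r.mean_frequency,
         ",".join(r.genes), ",".join(r.cytobands))
        for r in regions
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "direction", "peak_freq", "mean_freq", "genes", "cytobands",
    ])


def write_regions(regions: Iterable[RecurrentRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def plot_frequency(track: FrequencyTrack, path: str | Path, p: float = 0.30) -> None:
    """Genome-wide frequency plot: gains up in red, losses down in green."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = track.data.copy()
    offsets: dict[str, int] = {}
    running = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        offsets[chrom] = running - int(grp["start"].min())
        running += int(grp["end"].max() - grp["start"].min()) + 1
    df["x0"] = df.apply(lambda r: r["start"] + offsets[r["chrom"]], axis=1)
    df["x1"] = df.apply(lambda r: r["end"] + offsets[r["chrom"]], axis=1)

    fig, ax = plt.subplots(figsize=(14, 4))
    for _, r in df.iterrows():
        ax.fill_between([r["x0"], r["x1"]], 0, r["freq_gain"], color="red", linewidth=0)
        ax.fill_between([r["x0"], r["x1"]], 0, -r["freq_loss"], color="green", linewidth=0)
    ax.axhline(p, linestyle="--", color="black", linewidth=0.8)
    ax.axhline(-p, linestyle="--", color="black", linewidth=0.8)
    ax.set_ylim(-1, 1)
    ax.set_ylabel("fraction of samples (gain up, loss down)")
    ax.set_xlabel("genome position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Locus-level LOH reporting
# ---------------------------------------------------------------------------

def proportion_as_percent(k: int, n: int, decimals: int = 1) -> float:
    """Report a count fraction k/n as a percentage rounded to *decimals*."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("count must be between 0 and the denominator")
    return round(100.0 * k / n, decimals)


def locus_loh_summary(
    profiles: Sequence[SampleProfile], chrom: str, position: int
) -> dict:
    """Fraction of samples with LOH (minor allele 0, total >= 1) at a locus.

    Returns a dict with the LOH count ``k``, the number of informative
    samples ``n`` (those with a segment covering the locus), and the
    percentage rounded to one decimal.
    """
    k = n = 0
    for p in profiles:
        seg = next(
            (s for s in p.segments
             if s.chrom == chrom and s.start <= position <= s.end),
            None,
        )
        if seg is None:
            continue
        n += 1
        if seg.b == 0 and seg.c >= 1:
            k += 1
    if n == 0:
        logger.warning("no sample covers %s:%d", chrom, position)
        return {"k": 0, "n": 0, "percent": float("nan")}
    return {"k": k, "n": n, "percent": proportion_as_percent(k, n)}
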