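"""Synthetic ASCAT-like cohorts with known ground truth.

The generator emits what a downstream copy number pipeline actually
consumes: integer allele-specific segments per sample (the post-segmentation
world — no SNP intensities, BAF noise or subclonality), a matched log2
expression matrix with a configurable fraction of genes under genuine
dosage (cis) control, sample metadata, and truth tables recording every
injected event and every true cis gene.

Each sample draws a ploidy target from a mixture (defaults 2.0 / 3.5 / 5.5,
mimicking the near-diploid, near-triploid-plus and high-ploidy peaks seen
in tumor cohorts).  The baseline genome is built from that target: every
arm gets the integer floor of the target as total copies, and a random
fraction of arms (the target's fractional part) gets one extra copy, so the
length-weighted mean ploidy lands on the target.  Aberrations are then
layered on by Poisson-distributed counts per class: whole-arm gains/losses,
focal +/-1 events, focal-complex events (k alternating short segments),
LOH (minor allele to zero, copy-neutral half the time) and allelic
asymmetry (major allele +1 where the minor is retained).  Overlapping
events compose by applying copy deltas sequentially, flooring alleles at 0.

Expression for gene g in sample s is
``mu_g + beta_g * (c_gs - P_s) + Normal(0, sd)`` with ``beta_g = beta`` for
the chosen cis fraction of genes and 0 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    Arm,
    GeneAnnotation,
    GenomeLayout,
    SampleProfile,
    Segment,
)

logger = logging.getLogger("ascopy")

__all__ = [
    "GroupSpec",
    "SyntheticTruth",
    "Cohort",
    "generate_profile",
    "generate_cohort",
    "synthetic_gene_annotation",
    "demo_specs",
    "write_cohort",
]

# Aberrant-cell-fraction draw: clipped normal mimicking a cohort with mean
# purity just above one half and a wide spread.
_ACF_MEAN, _ACF_SD, _ACF_RANGE = 0.533, 0.15, (0.21, 1.0)


@dataclass(frozen=True)
class GroupSpec:
    """Event rates and ploidy mixture for one sample stratum."""

    name: str
    n_samples: int
    ploidy_means: tuple[float, ...] = (2.0, 3.5, 5.5)
    ploidy_weights: tuple[float, ...] = (0.55, 0.30, 0.15)
    arm_event_rate: float = 4.0        # whole-arm +/-1 events per genome
    focal_event_rate: float = 3.0      # single focal +/-1 events per genome
    focal_complex_rate: float = 1.5    # oscillating focal clusters per genome
    focal_length_range: tuple[int, int] = (100_000, 3_000_000)
    oscillation_range: tuple[int, int] = (3, 8)
    loh_rate: float = 2.0              # regional LOH events per genome
    asym_rate: float = 2.0             # regional allelic-asymmetry events
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in (self.arm_event_rate, self.focal_event_rate,
                  self.focal_complex_rate, self.loh_rate, self.asym_rate):
            if r < 0:
                raise ValueError("event rates must be >= 0")
        if abs(sum(self.ploidy_weights) - 1.0) > 1e-9:
            raise ValueError("ploidy mixture weights must sum to 1")
        if len(self.ploidy_means) != len(self.ploidy_weights):
            raise ValueError("ploidy means and weights must have equal length")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated cohort."""

    events: pd.DataFrame       # sample, chrom, start, end, type, detail
    cis_genes: pd.DataFrame    # gene, beta
    noise_sd: float
    seed: int


@dataclass
class Cohort:
    profiles: list[SampleProfile]
    expression: pd.DataFrame   # genes x samples, log2 scale
    metadata: pd.DataFrame     # indexed by sample
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Single-profile generation
# ---------------------------------------------------------------------------

def _split_apply(pieces: list[list], start: int, end: int,
                 fn: Callable[[int, int], tuple[int, int]]) -> None:
    """Apply fn(a0, a1) to the [start, end] slice of an arm's piece list."""
    out: list[list] = []
    for s, e, x, y in pieces:
        if e < start or s > end:
            out.append([s, e, x, y])
            continue
        if s < start:
            out.append([s, start - 1, x, y])
        lo, hi = max(s, start), min(e, end)
        nx, ny = fn(x, y)
        out.append([lo, hi, max(0, nx), max(0, ny)])
        if e > end:
            out.append([end + 1, e, x, y])
    pieces[:] = out


def _draw_interval(rng: np.random.Generator, arm: Arm, length: int) -> tuple[int, int]:
    length = min(length, arm.length)
    start = int(rng.integers(arm.start, arm.end - length + 2))
    return start, start + length - 1


def generate_profile(
    layout: GenomeLayout,
    spec: GroupSpec,
    seed: int | np.random.Generator,
    sample_id: str | None = None,
) -> tuple[SampleProfile, list[dict]]:
    """Simulate one ASCAT-like profile; returns the profile and its truth events."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample = sample_id or f"{spec.name}_s{rng.integers(0, 10**6)}"

    # baseline: integer part of the ploidy target everywhere, one extra copy
    # on a random fraction of arms equal to the fractional part
    comp = int(rng.choice(len(spec.ploidy_means), p=np.asarray(spec.ploidy_weights)))
    target = float(spec.ploidy_means[comp])
    base = int(np.floor(target))
    frac = target - base

    arm_pieces: dict[Arm, list[list]] = {}
    for arm in layout.arms:
        total = base + (1 if rng.random() < frac else 0)
        a0 = (total + 1) // 2
        arm_pieces[arm] = [[arm.start, arm.end, a0, total - a0]]

    events: list[dict] = []
    arms = list(layout.arms)

    def record(arm: Arm, start: int, end: int, etype: str, detail: str) -> None:
        events.append({
            "sample": sample, "chrom": arm.chrom, "start": start, "end": end,
            "type": etype, "detail": detail,
        })

    # whole-arm gains/losses
    for _ in range(rng.poisson(spec.arm_event_rate)):
        arm = arms[rng.integers(len(arms))]
        sign = 1 if rng.random() < 0.5 else -1
        allele = int(rng.integers(2))
        _split_apply(arm_pieces[arm], arm.start, arm.end,
                     lambda x, y, s=sign, al=allele:
                     (x + s, y) if al == 0 else (x, y + s))
        record(arm, arm.start, arm.end, "arm_gain" if sign > 0 else "arm_loss",
               f"allele{allele}{'+' if sign > 0 else '-'}1")

    # single focal events
    for _ in range(rng.poisson(spec.focal_event_rate)):
        arm = arms[rng.integers(len(arms))]
        length = int(rng.integers(spec.focal_length_range[0],
                                  spec.focal_length_range[1] + 1))
        if length > arm.length:
            logger.debug("focal event clipped to arm %s", arm.name)
        start, end = _draw_interval(rng, arm, length)
        sign = 1 if rng.random() < 0.5 else -1
        allele = int(rng.integers(2))
        _split_apply(arm_pieces[arm], start, end,
                     lambda x, y, s=sign, al=allele:
                     (x + s, y) if al == 0 else (x, y + s))
        record(arm, start, end, "focal_gain" if sign > 0 else "focal_loss",
               f"allele{allele}{'+' if sign > 0 else '-'}1")

    # focal-complex: k alternating +/-1 sub-segments
    for _ in range(rng.poisson(spec.focal_complex_rate)):
        arm = arms[rng.integers(len(arms))]
        k = int(rng.integers(spec.oscillation_range[0], spec.oscillation_range[1] + 1))
        total_len = int(rng.integers(spec.focal_length_range[0],
                                     spec.focal_length_range[1] + 1))
        sub = max(1, total_len // k)
        start, _ = _draw_interval(rng, arm, sub * k)
        sign = 1 if rng.random() < 0.5 else -1
        for j in range(k):
            if j % 2 == 0:
                continue  # alternate: every other sub-segment is shifted
            lo = start + j * sub
            hi = min(lo + sub - 1, arm.end)
            _split_apply(arm_pieces[arm], lo, hi,
                         lambda x, y, s=sign: (x + s, y))
        record(arm, start, min(start + sub * k - 1, arm.end), "focal_complex",
               f"k={k},allele0{'+' if sign > 0 else '-'}1")

    # LOH: minor allele to zero; copy-neutral (total preserved) half the time
    for _ in range(rng.poisson(spec.loh_rate)):
        arm = arms[rng.integers(len(arms))]
        length = int(rng.integers(1_000_000, arm.length + 1))
        start, end = _draw_interval(rng, arm, length)
        neutral = rng.random() < 0.5
        _split_apply(arm_pieces[arm], start, end,
                     lambda x, y, cn=neutral:
                     (x + y, 0) if cn else (max(x, y), 0))
        record(arm, start, end, "loh", "copy_neutral" if neutral else "simple")

    # allelic asymmetry: one extra copy of the larger allele where the other
    # allele is retained
    for _ in range(rng.poisson(spec.asym_rate)):
        arm = arms[rng.integers(len(arms))]
        length = int(rng.integers(1_000_000, arm.length + 1))
        start, end = _draw_interval(rng, arm, length)
        _split_apply(arm_pieces[arm], start, end,
                     lambda x, y: (max(x, y) + 1, min(x, y)) if min(x, y) >= 1 else (x, y))
        record(arm, start, end, "asym", "major+1")

    # assemble segments: order alleles major/minor and merge equal neighbours
    segments: list[Segment] = []
    for arm in layout.arms:
        merged: list[list] = []
        for s, e, x, y in arm_pieces[arm]:
            a, b = max(x, y), min(x, y)
            if merged and merged[-1][2] == a and merged[-1][3] == b and merged[-1][1] + 1 == s:
                merged[-1][1] = e
            else:
                merged.append([s, e, a, b])
        for s, e, a, b in merged:
            segments.append(Segment(sample, arm.chrom, s, e, a, b))

    lengths = np.array([s.length for s in segments], dtype=float)
    totals = np.array([s.c for s in segments], dtype=float)
    ploidy = float(np.sum(lengths * totals) / lengths.sum())
    acf = float(np.clip(rng.normal(_ACF_MEAN, _ACF_SD), *_ACF_RANGE))

    profile = SampleProfile(
        sample, segments, ploidy=ploidy, acf=acf,
        metadata={"group": spec.name, **spec.metadata},
    )
    return profile, events


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def synthetic_gene_annotation(
    layout: GenomeLayout,
    n_genes: int = 1000,
    seed: int | np.random.Generator = 0,
    gene_length: int = 50_000,
) -> list[GeneAnnotation]:
    """Place *n_genes* synthetic genes uniformly over the layout's arms.

    Cytoband labels are stand-ins (the arm name); real annotations carry
    UCSC band names instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arms = list(layout.arms)
    lengths = np.array([a.length for a in arms], dtype=float)
    probs = lengths / lengths.sum()
    genes: list[GeneAnnotation] = []
    for i in range(n_genes):
        arm = arms[int(rng.choice(len(arms), p=probs))]
        start = int(rng.integers(arm.start, max(arm.start + 1, arm.end - gene_length)))
        end = min(start + gene_length - 1, arm.end)
        genes.append(GeneAnnotation(f"G{i:05d}", arm.chrom, start, end, cytoband=arm.name))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def generate_cohort(
    layout: GenomeLayout,
    specs: Sequence[GroupSpec],
    annotation: Sequence[GeneAnnotation],
    cis_fraction: float = 0.2,
    beta: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> Cohort:
    """Simulate profiles for every group plus matched expression and truth.

    Expression for gene g, sample s is
    ``mu_g + beta_g * (c_gs - P_s) + N(0, noise_sd)``; genes without copy
    number coverage in a sample contribute no dosage term there.
    """
    if not annotation:
        raise ValueError("generate_cohort needs a non-empty gene annotation")
    if not 0.0 <= cis_fraction <= 1.0:
        raise ValueError("cis_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    profiles: list[SampleProfile] = []
    all_events: list[dict] = []
    for spec in specs:
        for i in range(spec.n_samples):
            profile, events = generate_profile(
                layout, spec, rng, sample_id=f"{spec.name}_{i:03d}")
            profiles.append(profile)
            all_events.extend(events)

    genes = list(annotation)
    n_cis = int(round(cis_fraction * len(genes)))
    cis_idx = set(rng.choice(len(genes), size=n_cis, replace=False).tolist())
    betas = np.array([beta if i in cis_idx else 0.0 for i in range(len(genes))])
    mu = rng.normal(7.0, 1.0, size=len(genes))

    copy = _copy_matrix(profiles, genes)  # genes x samples, NaN where uncovered
    ploidies = np.array([p.ploidy for p in profiles], dtype=float)
    dosage = copy.to_numpy() - ploidies[None, :]
    dosage = np.where(np.isnan(dosage), 0.0, dosage)
    noise = rng.normal(0.0, noise_sd, size=dosage.shape)
    expr_values = mu[:, None] + betas[:, None] * dosage + noise
    expression = pd.DataFrame(
        expr_values, index=[g.gene for g in genes],
        columns=[p.sample for p in profiles],
    )
    expression.index.name = "gene"

    meta_rows = []
    for p in profiles:
        meta_rows.append({"sample": p.sample, "ploidy": p.ploidy, "acf": p.acf,
                          **p.metadata})
    metadata = pd.DataFrame(meta_rows).set_index("sample")

    truth = SyntheticTruth(
        events=pd.DataFrame(
            all_events, columns=["sample", "chrom", "start", "end", "type", "detail"]),
        cis_genes=pd.DataFrame(
            {"gene": [genes[i].gene for i in sorted(cis_idx)],
             "beta": [beta] * len(cis_idx)}),
        noise_sd=noise_sd,
        seed=seed,
    )
    logger.info("generated cohort: %d samples, %d genes (%d cis)",
                len(profiles), len(genes), n_cis)
    return Cohort(profiles, expression, metadata, truth)


def _copy_matrix(profiles: Sequence[SampleProfile],
                 genes: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Gene-midpoint total copy number per sample (NaN where uncovered)."""
    from .cis_expression import _locus_copy_lookup

    out = _locus_copy_lookup(profiles, genes)
    return pd.DataFrame(out, index=[g.gene for g in genes],
                        columns=[p.sample for p in profiles])


def demo_specs(n_per_group: int = 30) -> list[GroupSpec]:
    """Two strata mirroring a high-burden mutated group vs a quieter one."""
    high = GroupSpec(
        name="TP53mut", n_samples=n_per_group,
        ploidy_means=(2.0, 3.5, 5.5), ploidy_weights=(0.35, 0.45, 0.20),
        arm_event_rate=12.0, focal_event_rate=8.0, focal_complex_rate=4.0,
        loh_rate=5.0, asym_rate=5.0,
        metadata={"TP53": "mutated", "histology": "adenocarcinoma"},
    )
    low = GroupSpec(
        name="TP53wt", n_samples=n_per_group,
        ploidy_means=(2.0, 3.5, 5.5), ploidy_weights=(0.70, 0.22, 0.08),
        arm_event_rate=4.0, focal_event_rate=2.5, focal_complex_rate=1.0,
        loh_rate=1.5, asym_rate=1.5,
        metadata={"TP53": "wildtype", "histology": "adenocarcinoma"},
    )
    return [high, low]


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write segments, expression, metadata and truth tables as TSVs."""
    from .genome_model import write_segment_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_segment_table(cohort.profiles, outdir / "segments.tsv")
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    cohort.truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    cohort.truth.cis_genes.to_csv(outdir / "truth_cis_genes.tsv", sep="\t", index=False)
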