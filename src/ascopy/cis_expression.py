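"""Copy-number / expression integration: cis-genes and gene-set enrichment.

For each gene, the total copy number of the segment containing the gene's
midpoint is matched with the gene's log2 expression per sample.  A gene is
a *cis-gene* when (i) the Pearson correlation between copy number and
expression exceeds 0.4, and (ii) at least one of two Welch t-tests is
significant at P < 0.05 without multiplicity correction: loss-vs-normal or
normal-vs-gain expression, with gain/loss/normal called relative to each
sample's ploidy using a delta = 0.5 copy band so a non-degenerate normal
class exists at non-integer ploidy.  The criterion is deliberately liberal.

The smaller t-test P-value is rescaled for display to Z = -F^{-1}(P), F the
standard normal CDF, so P < 0.05 corresponds to Z > 1.64.

Cis-gene lists are tested for gene-set enrichment with one-sided Fisher
exact tests on the 2x2 membership table, Benjamini-Hochberg corrected
across sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import GeneAnnotation, SampleProfile
from .ploidy_calls import GAIN, LOSS, NORMAL, resolve_ploidy
from .recurrence import RecurrentRegion

logger = logging.getLogger("ascopy")

__all__ = [
    "CisGeneRecord",
    "EnrichmentResult",
    "match_gene_copynumber",
    "cis_test",
    "pvals_to_z",
    "call_cis_genes",
    "cis_records_to_frame",
    "enrich_gene_sets",
    "enrichment_to_frame",
]

R_THRESHOLD = 0.4
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class CisGeneRecord:
    """Per-gene copy-number/expression integration result."""

    gene: str
    n: int
    r: float  # Pearson r, NaN when undefined
    p_loss: float  # loss vs normal, NaN when not testable
    p_gain: float  # normal vs gain, NaN when not testable
    min_p: float
    z: float
    cis: bool
    in_recurrent_region: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's Fisher enrichment against the cis-gene list."""

    gene_set: str
    universe_size: int
    set_size: int
    cis_count: int
    overlap: int
    p_raw: float
    p_adjusted: float


def match_gene_copynumber(
    gene: GeneAnnotation, profiles: Sequence[SampleProfile]
) -> pd.Series:
    """Per-sample total copy number of the segment containing the gene midpoint.

    Samples without a covering segment are NaN (missing).  A gene whose
    chromosome is absent from every profile yields an all-missing vector.
    """
    mid = gene.midpoint
    values: dict[str, float] = {}
    any_chrom = False
    for p in profiles:
        hit = float("nan")
        for s in p.segments:
            if s.chrom != gene.chrom:
                continue
            any_chrom = True
            if s.start <= mid <= s.end:
                hit = float(s.c)
                break
        values[p.sample] = hit
    if not any_chrom:
        logger.warning("gene %s: chromosome %s absent from all profiles", gene.gene, gene.chrom)
    return pd.Series(values, name=gene.gene)


def pvals_to_z(p: float) -> float:
    """Rescale a P-value to the standard-normal quantile scale, Z = -F^{-1}(P)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"P-value must be in (0, 1), got {p}")
    return float(-stats.norm.ppf(p))


def _welch(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def cis_test(
    copy: Sequence[float],
    expr: Sequence[float],
    calls: Sequence[str],
    gene: str = "",
    min_group: int = 3,
) -> CisGeneRecord:
    """Run the compound cis criterion for one gene.

    *copy*, *expr* and *calls* are aligned per-sample vectors; missing
    entries (NaN copy or expression) are excluded pairwise.  Each t-test
    runs only when both of its arms have >= *min_group* samples; a gene can
    qualify through either test.  Zero variance in copy number leaves the
    correlation undefined and the gene is not cis.
    """
    c = np.asarray(copy, dtype=float)
    e = np.asarray(expr, dtype=float)
    lab = np.asarray(calls, dtype=object)
    ok = ~(np.isnan(c) | np.isnan(e))
    c, e, lab = c[ok], e[ok], lab[ok]
    n = int(ok.sum())

    nan = float("nan")
    if n < 2 or np.ptp(c) == 0 or np.ptp(e) == 0:
        if n and np.ptp(c) == 0:
            logger.debug("gene %s: constant copy number, correlation undefined", gene)
        return CisGeneRecord(gene, n, nan, nan, nan, nan, nan, False)

    r = float(stats.pearsonr(c, e).statistic)

    e_loss = e[lab == LOSS]
    e_norm = e[lab == NORMAL]
    e_gain = e[lab == GAIN]
    p_loss = (
        _welch(e_loss, e_norm)
        if len(e_loss) >= min_group and len(e_norm) >= min_group else nan
    )
    p_gain = (
        _welch(e_norm, e_gain)
        if len(e_norm) >= min_group and len(e_gain) >= min_group else nan
    )
    ps = [p for p in (p_loss, p_gain) if not math.isnan(p)]
    min_p = min(ps) if ps else nan
    z = pvals_to_z(min_p) if ps and 0 < min_p < 1 else nan
    cis = bool(r > R_THRESHOLD and ps and min_p < P_THRESHOLD)
    return CisGeneRecord(gene, n, r, p_loss, p_gain, min_p, z, cis)


def _locus_copy_lookup(
    profiles: Sequence[SampleProfile], genes: Sequence[GeneAnnotation]
) -> np.ndarray:
    """Gene-midpoint total copy number, genes x profiles (NaN uncovered)."""
    out = np.full((len(genes), len(profiles)), np.nan)
    mids_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gi, g in enumerate(genes):
        mids_by_chrom.setdefault(g.chrom, []).append((g.midpoint, gi))
    for si, p in enumerate(profiles):
        segs_by_chrom: dict[str, list] = {}
        for s in p.segments:
            segs_by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, mids in mids_by_chrom.items():
            segs = segs_by_chrom.get(chrom)
            if not segs:
                continue
            starts = np.array([s.start for s in segs])
            ends = np.array([s.end for s in segs])
            totals = np.array([s.c for s in segs], dtype=float)
            pos = np.array([m for m, _ in mids])
            idx = np.searchsorted(starts, pos, side="right") - 1
            covered = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
            for (_, gi), i, good in zip(mids, idx, covered):
                if good:
                    out[gi, si] = totals[i]
    return out


def call_cis_genes(
    expr: pd.DataFrame,
    profiles: Sequence[SampleProfile],
    genes: Sequence[GeneAnnotation],
    regions: Sequence[RecurrentRegion] = (),
    delta: float = 0.5,
    min_samples: int = 10,
    min_group: int = 3,
) -> list[CisGeneRecord]:
    """Run the cis criterion over every annotated gene present in *expr*.

    *expr* is a gene x sample log2 matrix (already probe-collapsed).  Only
    samples shared between the expression matrix and the profiles are used;
    an empty intersection is an error.  Genes with fewer than *min_samples*
    matched pairs are reported with cis = False.  The
    located-in-recurrent-region flag is set by >= 1 bp overlap.
    """
    prof_by_sample = {p.sample: p for p in profiles}
    shared = [s for s in expr.columns if s in prof_by_sample]
    if not shared:
        raise ValueError("expression matrix and profiles share no sample ids")
    logger.info("call_cis_genes: %d shared samples, %d candidate genes",
                len(shared), len(genes))

    shared_profiles = [prof_by_sample[s] for s in shared]
    ploidy = np.array([resolve_ploidy(p) for p in shared_profiles])
    cand = [g for g in genes if g.gene in expr.index]
    copy_mat = _locus_copy_lookup(shared_profiles, cand)

    records: list[CisGeneRecord] = []
    for gi, gene in enumerate(cand):
        copies = pd.Series(copy_mat[gi], index=shared, name=gene.gene)
        evals = expr.loc[gene.gene, shared].astype(float)
        cvals = copies.to_numpy()
        calls = np.where(
            np.isnan(cvals), "missing",
            np.where(cvals > ploidy + delta, GAIN,
                     np.where(cvals < ploidy - delta, LOSS, NORMAL)),
        )
        n_pairs = int((~(copies.isna() | evals.isna())).sum())
        if n_pairs < min_samples:
            rec = CisGeneRecord(gene.gene, n_pairs, float("nan"), float("nan"),
                                float("nan"), float("nan"), float("nan"), False)
        else:
            rec = cis_test(copies.to_numpy(), evals.to_numpy(), calls,
                           gene=gene.gene, min_group=min_group)
        in_region = any(
            r.chrom == gene.chrom and gene.start <= r.end and gene.end >= r.start
            for r in regions
        )
        records.append(CisGeneRecord(
            rec.gene, rec.n, rec.r, rec.p_loss, rec.p_gain, rec.min_p, rec.z,
            rec.cis, in_region,
        ))
    return records


def cis_records_to_frame(records: Iterable[CisGeneRecord]) -> pd.DataFrame:
    rows = [
        (r.gene, r.n, r.r, r.p_loss, r.p_gain, r.min_p, r.z, r.cis, r.in_recurrent_region)
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "gene", "n", "r", "p_loss", "p_gain", "min_p", "z", "cis", "in_recurrent_region",
    ])


def enrich_gene_sets(
    cis: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of the cis list in each gene set.

    Sets are intersected with the universe; the 2x2 table per set is
    (in set / not) x (cis / not).  BH correction is applied across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    cis_set = set(cis) & uni
    if set(cis) - uni:
        logger.warning("enrich_gene_sets: %d cis genes outside the universe ignored",
                       len(set(cis) - uni))

    names, praw = [], []
    tables = []
    for name, members in gene_sets.items():
        in_set = set(members) & uni
        overlap = len(in_set & cis_set)
        table = [
            [overlap, len(cis_set) - overlap],
            [len(in_set) - overlap, len(uni) - len(in_set) - len(cis_set) + overlap],
        ]
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        names.append(name)
        praw.append(p)
        tables.append((len(in_set), overlap))
    if not names:
        return []
    p_adj = multipletests(praw, method="fdr_bh")[1]
    return [
        EnrichmentResult(name, len(uni), size, len(cis_set), overlap, p, float(pa))
        for name, (size, overlap), p, pa in zip(names, tables, praw, p_adj)
    ]


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.gene_set, r.universe_size, r.set_size, r.cis_count, r.overlap,
         r.p_raw, r.p_adjusted)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "gene_set", "universe", "set_size", "cis_count", "overlap", "p_raw", "p_adjusted",
    ])


def write_cis_table(records: Iterable[CisGeneRecord], path: str | Path) -> None:
    cis_records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    enrichment_to_frame(results).to_csv(path, sep="\t", index=False)
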