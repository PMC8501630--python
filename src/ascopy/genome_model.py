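"""Core data types, genome/arm layout, and readers/writers.

Coordinate convention
---------------------
All internal coordinates are 1-based inclusive, matching the segment-table
dialect emitted by allele-specific copy number callers such as ASCAT.  BED
input (0-based half-open) is converted at the boundary on read and write.

Chromosome names are normalised by stripping any leading ``chr`` prefix;
``23``/``24`` are mapped to ``X``/``Y``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ascopy")

__all__ = [
    "Arm",
    "GenomeLayout",
    "Segment",
    "SampleProfile",
    "GeneAnnotation",
    "ValidationError",
    "ParseError",
    "normalize_chromosome",
    "read_segment_table",
    "write_segment_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_expression",
    "read_probe_map",
    "collapse_probes",
    "read_metadata",
    "read_gmt",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (coordinates, overlap, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def normalize_chromosome(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    return c


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Arm:
    """One chromosome arm, 1-based inclusive coordinates."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"arm {self.chrom}{self.arm}: end {self.end} < start {self.start}"
            )

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# hg19 arm boundaries derived from the UCSC centromere gap table.  The five
# acrocentric p-arms (13p, 14p, 15p, 21p, 22p) carry no copy number calls on
# SNP arrays and are omitted, leaving 24 x 2 - 5 = 43 arms.
_HG19 = {
    # chrom: (centromere start, centromere end, chromosome length)
    "1": (121535434, 124535434, 249250621),
    "2": (92326171, 95326171, 243199373),
    "3": (90504854, 93504854, 198022430),
    "4": (49660117, 52660117, 191154276),
    "5": (46405641, 49405641, 180915260),
    "6": (58830166, 61830166, 171115067),
    "7": (58054331, 61054331, 159138663),
    "8": (43838887, 46838887, 146364022),
    "9": (47367679, 50367679, 141213431),
    "10": (39254935, 42254935, 135534747),
    "11": (51644205, 54644205, 135006516),
    "12": (34856694, 37856694, 133851895),
    "13": (16000000, 19000000, 115169878),
    "14": (16000000, 19000000, 107349540),
    "15": (17000000, 20000000, 102531392),
    "16": (35335801, 38335801, 90354753),
    "17": (22263006, 25263006, 81195210),
    "18": (15460898, 18460898, 78077248),
    "19": (24681782, 27681782, 59128983),
    "20": (26369569, 29369569, 63025520),
    "21": (11288129, 14288129, 48129895),
    "22": (13000000, 16000000, 51304566),
    "X": (58632012, 61632012, 155270560),
    "Y": (10104553, 13104553, 59373566),
}
_ACROCENTRIC = {"13", "14", "15", "21", "22"}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome-arm table defining the reference genome."""

    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        seen: dict[str, list[Arm]] = {}
        for a in self.arms:
            seen.setdefault(a.chrom, []).append(a)
        for chrom, arms in seen.items():
            if len(arms) == 2:
                p, q = arms
                if p.arm != "p" or q.arm != "q":
                    raise ValidationError(f"chromosome {chrom}: arms not ordered p before q")
                if p.end >= q.start:
                    raise ValidationError(f"chromosome {chrom}: arms overlap")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        out: list[str] = []
        for a in self.arms:
            if a.chrom not in out:
                out.append(a.chrom)
        return tuple(out)

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def chromosome_length(self, chrom: str) -> int:
        arms = [a for a in self.arms if a.chrom == chrom]
        if not arms:
            raise KeyError(chrom)
        return max(a.end for a in arms)

    def arms_of(self, chrom: str) -> tuple[Arm, ...]:
        return tuple(a for a in self.arms if a.chrom == chrom)

    @classmethod
    def default(cls, include_y: bool = True) -> "GenomeLayout":
        """The packaged hg19-style layout: 43 arms over chr1-22, X and Y."""
        arms: list[Arm] = []
        for chrom, (cen_start, cen_end, length) in _HG19.items():
            if not include_y and chrom == "Y":
                continue
            if chrom not in _ACROCENTRIC:
                arms.append(Arm(chrom, "p", 1, cen_start))
            arms.append(Arm(chrom, "q", cen_end + 1, length))
        return cls(tuple(arms))

    @classmethod
    def from_arm_table(cls, path: str | Path) -> "GenomeLayout":
        """Read a 4-column arm TSV: chrom, arm, start, end (1-based inclusive)."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
        arms = [
            Arm(normalize_chromosome(r["chrom"]), str(r["arm"]), int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()
        ]
        return cls(tuple(arms))

    @classmethod
    def from_cytoband(cls, path: str | Path) -> "GenomeLayout":
        """Build arms from a UCSC cytoBand.txt file (0-based half-open bands)."""
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "band", "stain"], dtype={"chrom": str},
        )
        df["chrom"] = df["chrom"].map(normalize_chromosome)
        df["armlab"] = df["band"].astype(str).str[0]
        arms: list[Arm] = []
        for (chrom, lab), grp in df.groupby(["chrom", "armlab"], sort=False):
            if lab not in ("p", "q"):
                continue
            arms.append(Arm(chrom, lab, int(grp["start"].min()) + 1, int(grp["end"].max())))
        arms.sort(key=lambda a: (_chrom_rank(a.chrom), a.arm))
        return cls(tuple(arms))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.chrom, a.arm, a.start, a.end) for a in self.arms],
            columns=["chrom", "arm", "start", "end"],
        )


def _chrom_rank(chrom: str) -> int:
    try:
        return int(chrom)
    except ValueError:
        return {"X": 23, "Y": 24}.get(chrom, 99)


# ---------------------------------------------------------------------------
# Segments and sample profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One allele-specific copy number segment.

    ``a`` is the major-allele and ``b`` the minor-allele copy number
    (integers, a >= b >= 0); the total ``c = a + b`` is derived.
    """

    sample: str
    chrom: str
    start: int
    end: int
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: end < start"
            )
        if not (self.a >= self.b >= 0):
            raise ValidationError(
                f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: "
                f"requires major >= minor >= 0, got ({self.a},{self.b})"
            )

    @property
    def c(self) -> int:
        return self.a + self.b

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleProfile:
    """One tumor's ordered segments plus ploidy, purity and metadata.

    ``ploidy`` is the supplied (caller-estimated) value when present; the
    length-weighted-median estimate is computed on demand downstream.
    ``acf`` is the aberrant cell fraction in [0, 1].
    """

    sample: str
    segments: list[Segment]
    ploidy: float | None = None
    acf: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ploidy is not None and not self.ploidy > 0:
            raise ValidationError(f"sample {self.sample}: ploidy must be > 0")
        if self.acf is not None and not (0.0 <= self.acf <= 1.0):
            raise ValidationError(f"sample {self.sample}: aberrant cell fraction not in [0,1]")
        self.segments = sorted(self.segments, key=lambda s: (_chrom_rank(s.chrom), s.start))
        _check_no_overlap(self.segments)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.segments:
            if s.chrom not in out:
                out.append(s.chrom)
        return tuple(out)


def _check_no_overlap(segments: Sequence[Segment]) -> None:
    prev: Segment | None = None
    for s in segments:
        if prev is not None and s.chrom == prev.chrom and s.start <= prev.end:
            raise ValidationError(
                f"sample {s.sample}: overlapping segments on chromosome {s.chrom}: "
                f"{prev.start}-{prev.end} and {s.start}-{s.end}"
            )
        prev = s


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's location (1-based inclusive) and optional cytoband label."""

    gene: str
    chrom: str
    start: int
    end: int
    cytoband: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"gene {self.gene}: end < start")
        if self.start < 1:
            raise ValidationError(f"gene {self.gene}: non-positive start coordinate")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = ("sample", "chr", "startpos", "endpos", "nMajor", "nMinor")


def read_segment_table(path: str | Path, layout: GenomeLayout) -> list[SampleProfile]:
    """Read an ASCAT-style tab-delimited segment table into sample profiles.

    Expected header: ``sample chr startpos endpos nMajor nMinor`` with
    optional per-sample ``ploidy`` and ``acf`` columns.  Chromosomes absent
    from *layout* are rejected.  Raises :class:`ParseError` for malformed
    rows (naming the line) and :class:`ValidationError` for invariant
    violations (end < start, overlap, unknown chromosome).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    known = set(layout.chromosomes)
    per_sample: dict[str, list[Segment]] = {}
    ploidies: dict[str, float] = {}
    acfs: dict[str, float] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            sample = str(row["sample"])
            chrom = normalize_chromosome(row["chr"])
            start, end = int(row["startpos"]), int(row["endpos"])
            a, b = int(row["nMajor"]), int(row["nMinor"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{line_no}: malformed row ({exc})") from exc
        if chrom not in known:
            raise ValidationError(f"{path}:{line_no}: unknown chromosome {chrom!r}")
        if end < start:
            raise ValidationError(f"{path}:{line_no}: end {end} < start {start}")
        per_sample.setdefault(sample, []).append(Segment(sample, chrom, start, end, a, b))
        if "ploidy" in df.columns and pd.notna(row["ploidy"]) and str(row["ploidy"]) != "":
            ploidies[sample] = float(row["ploidy"])
        if "acf" in df.columns and pd.notna(row["acf"]) and str(row["acf"]) != "":
            acfs[sample] = float(row["acf"])

    profiles = [
        SampleProfile(sample, segs, ploidy=ploidies.get(sample), acf=acfs.get(sample))
        for sample, segs in per_sample.items()
    ]
    logger.info("read %d profiles (%d segments) from %s", len(profiles), len(df), path)
    return profiles


def write_segment_table(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    """Write profiles back to the tab-delimited segment-table dialect."""
    rows = []
    any_ploidy = any(p.ploidy is not None for p in profiles)
    any_acf = any(p.acf is not None for p in profiles)
    for p in profiles:
        for s in p.segments:
            row = {
                "sample": p.sample, "chr": s.chrom, "startpos": s.start,
                "endpos": s.end, "nMajor": s.a, "nMinor": s.b,
            }
            if any_ploidy:
                row["ploidy"] = "" if p.ploidy is None else p.ploidy
            if any_acf:
                row["acf"] = "" if p.acf is None else p.acf
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED4+1 gene annotation (chrom, start, end, name[, cytoband]).

    BED is 0-based half-open; records are converted to the internal 1-based
    inclusive convention.  Duplicate gene symbols raise an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("gene annotation %s is empty", path)
        return []
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected at least 4 BED columns, got {df.shape[1]}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line_no = idx + 1
        try:
            chrom = normalize_chromosome(row[0])
            bed_start, bed_end = int(row[1]), int(row[2])
            name = str(row[3])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{line_no}: malformed BED row ({exc})") from exc
        if bed_start < 0:
            raise ValidationError(f"{path}:{line_no}: negative coordinate")
        if name in seen:
            raise ValidationError(f"{path}:{line_no}: duplicate gene symbol {name!r}")
        seen.add(name)
        cytoband = str(row[4]) if df.shape[1] > 4 and pd.notna(row[4]) else None
        genes.append(GeneAnnotation(name, chrom, bed_start + 1, bed_end, cytoband))
    genes.sort(key=lambda g: (_chrom_rank(g.chrom), g.start))
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write genes as BED4+1 (back to 0-based half-open)."""
    rows = [
        (g.chrom, g.start - 1, g.end, g.gene, "" if g.cytoband is None else g.cytoband)
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a log2 expression TSV (first column probe/gene id, rest samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample columns")
    return df


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column probe-to-gene TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df[0], df[1]))


def collapse_probes(expr: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level log2 matrix to gene level.

    Probes with no gene mapping are dropped; a gene measured by several
    probes gets the arithmetic mean of their log2 values per sample.
    """
    mapped = [p for p in expr.index if p in probe_to_gene]
    if not mapped:
        raise ValidationError("no probes in the expression matrix have a gene mapping")
    dropped = expr.shape[0] - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", dropped)
    sub = expr.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene")
    out = sub.groupby(genes).mean()
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV, indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ParseError(f"{path}: metadata table needs a 'sample' column")
    return df.set_index("sample")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{line_no}: GMT line has fewer than 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
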