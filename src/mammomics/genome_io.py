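"""Genomic coordinate model and readers/writers for the external formats.

All coordinates are 0-based half-open internally (BED convention). Formats
that are 1-based on disk (the per-CpG count table) are converted at the
parser boundary, so downstream code never sees mixed conventions. Overlap
between two intervals means >= 1 shared base pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> float:
        """Gap between nearest ends; 0 if overlapping; inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exon structure and a strand-aware TSS."""

    gene_id: str
    name: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    is_protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError("gene body must be stranded (+ or -)")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.body.chrom or e.start < self.body.start or e.end > self.body.end:
                raise ValueError(f"exon {e} outside gene body {self.body}")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        object.__setattr__(self, "exons", exons)

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: body.start on +, body.end - 1 on -."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    def promoter(self, upstream: int = 2500) -> GenomicInterval:
        """Strand-aware promoter window of ``upstream`` bp ending at the TSS."""
        if self.strand == "+":
            start = max(0, self.body.start - upstream)
            end = self.body.start
            if end <= start:  # TSS at chromosome origin
                end = start + 1
        else:
            start = self.body.end
            end = self.body.end + upstream
        return GenomicInterval(self.body.chrom, start, end, self.strand)

    def window_with_upstream(self, upstream: int = 2500) -> GenomicInterval:
        """Gene body extended ``upstream`` bp 5' of the TSS (strand-aware)."""
        if self.strand == "+":
            return GenomicInterval(
                self.body.chrom, max(0, self.body.start - upstream), self.body.end, "+"
            )
        return GenomicInterval(
            self.body.chrom, self.body.start, self.body.end + upstream, "-"
        )


@dataclass
class CpGSite:
    """One CpG with per-sample methylated/unmethylated read counts.

    ``beta`` is methylated / (methylated + unmethylated), NaN where a sample
    has zero coverage.
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    meth: np.ndarray  # shape (n_samples,), int
    unmeth: np.ndarray

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.unmeth = np.asarray(self.unmeth, dtype=np.int64)
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth/unmeth count vectors differ in length")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ParseError(f"negative counts at {self.chrom}:{self.pos}")

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def beta(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)
        return b

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, self.strand)


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over ACGT.

    ``matrix`` has shape (length, 4) with rows summing to 1; scores are
    log2 odds against ``background``. ``score_threshold`` (bits) defaults to
    80% of the maximum achievable score.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if self.score_threshold is None:
            self.score_threshold = 0.8 * self.max_score()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(length, 4) matrix of log2(p_base / background_base)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.score_threshold,
        )


@dataclass
class AnnotationSet:
    """Gene models plus CpG-island intervals, with per-chromosome indexing."""

    genes: list[GeneModel]
    cgi: list[GenomicInterval]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids must be unique")
        self.cgi = sorted(self.cgi, key=lambda i: (i.chrom, i.start))

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in sorted(self.genes, key=lambda g: (g.body.chrom, g.body.start)):
            out.setdefault(g.body.chrom, []).append(g)
        return out

    def cgi_by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for i in self.cgi:
            out.setdefault(i.chrom, []).append(i)
        return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into half-open intervals, preserving order.

    ``track``/``browser``/``#`` lines are skipped. Malformed coordinates
    raise :class:`ParseError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
) -> None:
    """Write BED; 6 columns when names or strands are informative, else 3."""
    with_extras = names is not None or any(i.strand != "." for i in intervals)
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            if with_extras:
                name = names[k] if names is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# per-CpG count table
# ---------------------------------------------------------------------------


def read_beta_table(path: str | Path) -> tuple[list[str], list[CpGSite]]:
    """Read a per-CpG count TSV into sites; returns (sample_names, sites).

    Expected columns: ``chrom``, ``pos`` (1-based on disk), ``strand``, then
    ``<sample>_meth`` / ``<sample>_unmeth`` pairs. Beta values are derived
    lazily from the counts; zero-coverage samples yield NaN beta.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    meth_cols = [c for c in df.columns if c.endswith("_meth")]
    samples = [c[: -len("_meth")] for c in meth_cols]
    for s in samples:
        if f"{s}_unmeth" not in df.columns:
            raise ParseError(f"{path}: sample {s} lacks an _unmeth column")
    if not samples:
        raise ParseError(f"{path}: no <sample>_meth/<sample>_unmeth column pairs")
    meth = df[[f"{s}_meth" for s in samples]].to_numpy()
    unmeth = df[[f"{s}_unmeth" for s in samples]].to_numpy()
    if (meth < 0).any() or (unmeth < 0).any():
        raise ParseError(f"{path}: negative counts")
    sites = [
        CpGSite(
            chrom=str(row.chrom),
            pos=int(row.pos) - 1,  # 1-based on disk -> 0-based internal
            strand=str(row.strand),
            meth=meth[i],
            unmeth=unmeth[i],
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    return samples, sites


def write_beta_table(
    path: str | Path, samples: Sequence[str], sites: Iterable[CpGSite]
) -> None:
    cols = ["chrom", "pos", "strand"]
    for s in samples:
        cols += [f"{s}_meth", f"{s}_unmeth"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for site in sites:
            row = [site.chrom, str(site.pos + 1), site.strand]
            for k in range(len(samples)):
                row += [str(int(site.meth[k])), str(int(site.unmeth[k]))]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gene annotation table
# ---------------------------------------------------------------------------

_GENE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "gene_id",
    "name",
    "biotype",
    "exon_starts",
    "exon_ends",
]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the BED-like gene annotation TSV (0-based half-open, like BED)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise ParseError(f"{path}: exon_starts/exon_ends mismatch for {row.gene_id}")
        exons = tuple(
            GenomicInterval(row.chrom, s, e, row.strand)
            for s, e in zip(starts, ends)
        )
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                name=str(row.name),
                body=body,
                exons=exons,
                is_protein_coding=(row.biotype == "protein_coding"),
            )
        )
    return genes


def write_gene_table(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.body.chrom,
                        str(g.body.start),
                        str(g.body.end),
                        g.strand,
                        g.gene_id,
                        g.name,
                        "protein_coding" if g.is_protein_coding else "other",
                        ",".join(str(e.start) for e in g.exons),
                        ",".join(str(e.end) for e in g.exons),
                    ]
                )
                + "\n"
            )


def load_annotation(gene_path: str | Path, cgi_path: str | Path) -> AnnotationSet:
    return AnnotationSet(genes=read_gene_table(gene_path), cgi=read_bed(cgi_path))


# ---------------------------------------------------------------------------
# PWM (JASPAR-style)
# ---------------------------------------------------------------------------

PWM_PSEUDOCOUNT = 0.25  # added per cell when converting counts to probabilities


def read_pwm(path: str | Path) -> list[PWM]:
    """Read JASPAR-style PFM blocks into :class:`PWM` objects.

    Count matrices are converted to probabilities with a +0.25 pseudocount
    per cell; matrices whose columns already sum to 1 are taken as
    probabilities and left unchanged. An empty file yields an empty list.
    """
    text = Path(path).read_text()
    if not text.strip():
        logger.warning("PWM file %s is empty", path)
        return []
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            parsed = [
                (m.matrix_id or m.name, np.array(
                    [m.counts[b] for b in BASES], dtype=float).T)
                for m in records
            ]
        except Exception as exc:
            raise ParseError(f"{path}: not a valid JASPAR-style PWM file: {exc}") from exc
    out = []
    for motif_id, mat in parsed:
        col_sums = mat.sum(axis=1)
        if np.allclose(col_sums, 1.0, atol=1e-6):
            prob = mat
        else:
            prob = (mat + PWM_PSEUDOCOUNT) / (
                (col_sums + 4 * PWM_PSEUDOCOUNT)[:, None]
            )
        out.append(PWM(motif_id=str(motif_id), matrix=prob))
    return out


def write_pwm(path: str | Path, pwms: Sequence[PWM], as_counts_scale: int = 100) -> None:
    """Write PWMs as JASPAR PFM count blocks (probabilities x scale)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            counts = np.round(p.matrix * as_counts_scale).astype(int)
            for bi, base in enumerate(BASES):
                row = " ".join(str(int(c)) for c in counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def open_genome(path: str | Path) -> Fasta:
    """Open a FASTA for random access (indexed on first use)."""
    return Fasta(str(path), sequence_always_upper=True)


def fetch_sequence(genome: Fasta, interval: GenomicInterval) -> str:
    """Fetch the forward-strand sequence of ``interval`` (uppercase)."""
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom} absent from genome")
    chrom_len = len(genome[interval.chrom])
    if interval.end > chrom_len:
        raise ValueError(
            f"interval {interval} exceeds chromosome length {chrom_len}"
        )
    return str(genome[interval.chrom][interval.start : interval.end])


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
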