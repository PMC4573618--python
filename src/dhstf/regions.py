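"""Genomic intervals: regulatory windows, DHS overlap, the indicator matrix C.

Coordinates follow the BED convention throughout: 0-based, half-open
[start, end). The regulatory region of a gene is the strand-aware window
spanning ``upstream`` bp before and ``downstream`` bp after the TSS
(defaults 1000 and 500). C[i, j] = 1 marks that DHS site j overlaps the
regulatory region of differentially expressed gene i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import EmptyInputError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int  # 0-based position of the transcription start site

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass
class IndicatorMatrix:
    """Binary gene x DHS membership matrix (C)."""

    gene_ids: list[str]
    dhs_ids: list[str]
    values: np.ndarray  # (n_genes, n_dhs) of 0/1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.dhs_ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "IndicatorMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=[str(i) for i in df.index],
            dhs_ids=[str(c) for c in df.columns],
            values=df.to_numpy(np.uint8),
        )


def regulatory_region(
    gene: GeneModel, upstream: int = 1000, downstream: int = 500
) -> GenomicInterval:
    """Strand-aware TSS window, clipped at the chromosome origin."""
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be nonnegative")
    if upstream == 0 and downstream == 0:
        raise ValueError("window has zero extent")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; strand is ignored."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def _dhs_trees(dhs: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(dhs):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees


def build_indicator_matrix(
    regions: Mapping[str, GenomicInterval],
    dhs: Sequence[GenomicInterval],
    mode: str = "any",
) -> IndicatorMatrix:
    """Mark which DHS sites fall in which regulatory regions.

    ``mode="any"`` (default) counts any overlap, since DHS sites routinely
    straddle window edges; ``mode="contained"`` requires the DHS to lie
    fully inside the window.
    """
    if not regions or not dhs:
        raise EmptyInputError("regions and DHS sets must be nonempty")
    if mode not in {"any", "contained"}:
        raise ValueError(f"unknown overlap mode {mode!r}")
    gene_ids = list(regions)
    dhs_ids = [iv.id for iv in dhs]
    values = np.zeros((len(gene_ids), len(dhs)), dtype=np.uint8)
    trees = _dhs_trees(dhs)
    for i, gid in enumerate(gene_ids):
        region = regions[gid]
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(region.start, region.end):
            j = hit.data
            if mode == "contained" and not contains(region, dhs[j]):
                continue
            values[i, j] = 1
    return IndicatorMatrix(gene_ids=gene_ids, dhs_ids=dhs_ids, values=values)


def overlap_fraction(
    peaks: Sequence[GenomicInterval], dhs: Sequence[GenomicInterval]
) -> float:
    """Fraction of peaks overlapping at least one DHS interval."""
    if not peaks:
        raise EmptyInputError("peak list is empty")
    trees = _dhs_trees(dhs)
    n_hit = sum(
        1
        for p in peaks
        if p.chrom in trees and trees[p.chrom].overlaps(p.start, p.end)
    )
    return n_hit / len(peaks)


# ---------------------------------------------------------------------------
# file input


def read_bed(path, strip_chr: bool = False) -> list[GenomicInterval]:
    """Read BED3+ into intervals (column 6 used as strand when present)."""
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 columns")
        chrom = fields[0]
        if strip_chr and chrom.startswith("chr"):
            chrom = chrom[3:]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        intervals.append(GenomicInterval(chrom, start, end, strand))
    if not intervals:
        raise EmptyInputError(f"no intervals in {path}")
    return intervals


def genes_from_bed(path, strip_chr: bool = False) -> list[GeneModel]:
    """Gene models from BED6: TSS is start on +, end-1 on -."""
    genes = []
    for iv, name in _bed_with_names(path, strip_chr):
        if iv.strand not in "+-":
            raise ParseError(f"gene {name}: BED gene records need a strand column")
        tss = iv.start if iv.strand == "+" else iv.end - 1
        genes.append(GeneModel(name, iv.chrom, iv.strand, tss))
    return _most_upstream_per_gene(genes)


def _bed_with_names(path, strip_chr):
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: need at least 4 columns (name)")
        chrom = fields[0][3:] if strip_chr and fields[0].startswith("chr") else fields[0]
        strand = fields[5] if len(fields) >= 6 else "."
        out.append(
            (GenomicInterval(chrom, int(fields[1]), int(fields[2]), strand), fields[3])
        )
    if not out:
        raise EmptyInputError(f"no records in {path}")
    return out


def read_gene_table(path, strip_chr: bool = False) -> list[GeneModel]:
    """Read gene models from a refFlat-style table or a simple headered TSV.

    Simple dialect (header required): columns gene_id, chrom, strand, tss.
    refFlat dialect (no header): geneName, name, chrom, strand, txStart,
    txEnd, ... — the TSS is txStart on + and txEnd-1 on -. When a gene has
    several transcripts the most upstream TSS is used, giving one regulatory
    region per gene.
    """
    text = Path(path).read_text().splitlines()
    if not text:
        raise EmptyInputError(f"no records in {path}")
    header = text[0].rstrip("\n").split("\t")
    genes: list[GeneModel] = []
    if {"gene_id", "chrom", "strand", "tss"}.issubset(header):
        df = pd.read_csv(path, sep="\t")
        for rec in df.itertuples(index=False):
            chrom = str(rec.chrom)
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            genes.append(GeneModel(str(rec.gene_id), chrom, rec.strand, int(rec.tss)))
    else:
        for lineno, line in enumerate(text, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: refFlat-style rows need >= 6 columns"
                )
            name, chrom, strand = fields[0], fields[2], fields[3]
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            tx_start, tx_end = int(fields[4]), int(fields[5])
            tss = tx_start if strand == "+" else tx_end - 1
            genes.append(GeneModel(name, chrom, strand, tss))
    return _most_upstream_per_gene(genes)


def _most_upstream_per_gene(genes: Iterable[GeneModel]) -> list[GeneModel]:
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None:
            best[g.gene_id] = g
        elif g.strand == "+" and g.tss < cur.tss:
            best[g.gene_id] = g
        elif g.strand == "-" and g.tss > cur.tss:
            best[g.gene_id] = g
    return list(best.values())
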