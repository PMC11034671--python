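"""Readers and writers for the genomic text formats the pipeline touches.

Coordinate conventions are handled strictly and in one place:

* all *internal* coordinates are 0-based, half-open;
* on-disk BED and bedGraph are 0-based, half-open;
* on-disk GTF-lite is 1-based, closed;
* Bismark coverage positions are 1-based with ``start == end`` (the dialect
  emitted by the Bismark methylation extractor).

The converters between these conventions are mutually inverse, and every
reader validates enough to fail loudly with the offending line number.
Gzip-compressed files (``.gz``) are read and written transparently.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Intervals / BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


class BedParseError(ValueError):
    pass


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into a list of :class:`GenomicInterval`.

    Missing optional columns default to name ``"."``, score ``0``,
    strand ``"."``. Malformed lines raise :class:`BedParseError` naming the
    1-based line number.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / coverage
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Piecewise-constant per-base coverage with fast window integrals.

    Built from bedGraph-style ``(chrom, start, end, value)`` segments.
    Positions not covered by any segment have value 0. Window sums are
    computed from a cumulative integral over segment breakpoints, so a
    query is O(log n_segments).
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if start >= end:
                raise ValueError(f"empty coverage segment {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, segs in per_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage segments on {chrom}")
            values = np.array([v for _, _, v in segs], dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values
            self._cum[chrom] = cum

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def _integral_to(self, chrom: str, pos: int) -> float:
        """Integral of coverage over [0, pos)."""
        starts, ends, cum = self._starts[chrom], self._ends[chrom], self._cum[chrom]
        i = int(np.searchsorted(ends, pos, side="left"))
        if i == len(ends):
            return float(cum[-1])
        total = float(cum[i])
        if pos > starts[i]:
            total += float(self._values[chrom][i]) * (pos - starts[i])
        return total

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if start >= end:
            raise ValueError("require start < end")
        if chrom not in self._starts:
            return 0.0
        return self._integral_to(chrom, end) - self._integral_to(chrom, start)

    def mean(self, chrom: str, start: int, end: int) -> float:
        return self.integral(chrom, start, end) / (end - start)

    def segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            ):
                yield chrom, int(s), int(e), float(v)

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        """Pointwise sum of two tracks (used to pool replicates)."""
        merged: list[tuple[str, int, int, float]] = []
        chroms = set(self.chroms) | set(other.chroms)
        for chrom in sorted(chroms):
            cuts = set()
            for track in (self, other):
                if chrom in track._starts:
                    cuts.update(track._starts[chrom].tolist())
                    cuts.update(track._ends[chrom].tolist())
            cuts = sorted(cuts)
            for a, b in zip(cuts[:-1], cuts[1:]):
                v = 0.0
                for track in (self, other):
                    if chrom in track._starts:
                        v += track.mean(chrom, a, b)
                if v != 0.0:
                    merged.append((chrom, a, b, v))
        return CoverageTrack(merged)


def read_bedgraph(path) -> CoverageTrack:
    segs = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: need 4 columns")
            segs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return CoverageTrack(segs)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end, value in track.segments():
            v = f"{value:g}"
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")


# ---------------------------------------------------------------------------
# Bismark coverage (CpG methylation calls)
# ---------------------------------------------------------------------------

@dataclass
class CpGRecord:
    """One CpG locus from a Bismark coverage file (1-based position).

    The percent-methylation field of the file is advisory; the methylated /
    unmethylated read counts are authoritative and the score is recomputed
    from them.
    """

    chrom: str
    position: int  # 1-based, as in the Bismark dialect
    count_m: int
    count_u: int

    @property
    def coverage(self) -> int:
        return self.count_m + self.count_u

    @property
    def score(self) -> float:
        """Percent methylation, 100 * M / (M + U)."""
        return 100.0 * self.count_m / self.coverage


def read_bismark_coverage(path, percent_tolerance: float = 0.1) -> list[CpGRecord]:
    """Parse a Bismark coverage file (chrom, start, end, %, count_M, count_U).

    Zero-coverage rows raise; a percent field disagreeing with the counts by
    more than ``percent_tolerance`` emits a warning and the recomputed value
    wins (it is never stored anyway).
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}: line {lineno}: need 6 columns")
            chrom, start = fields[0], int(fields[1])
            count_m, count_u = int(fields[4]), int(fields[5])
            if count_m + count_u == 0:
                raise ValueError(
                    f"{path}: line {lineno}: zero-coverage CpG at {chrom}:{start}"
                )
            rec = CpGRecord(chrom, start, count_m, count_u)
            file_pct = float(fields[3])
            if abs(file_pct - rec.score) > percent_tolerance:
                warnings.warn(
                    f"{path}: line {lineno}: percent field {file_pct} disagrees "
                    f"with counts ({rec.score:.4f}); counts win"
                )
            out.append(rec)
    return out


def write_bismark_coverage(records: Iterable[CpGRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position}\t{r.score:.6g}"
                f"\t{r.count_m}\t{r.count_u}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation (GTF-lite)
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """A gene with internal 0-based half-open coordinates.

    ``tss`` is the gene start on the + strand and ``end - 1`` on the -
    strand. Exons are non-overlapping intervals within the gene body.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for (a, b) in self.exons:
            if a < self.start or b > self.end:
                raise ValueError(f"exon outside gene body for {self.gene_id}")
        ex = sorted(self.exons)
        for (a1, b1), (a2, b2) in zip(ex[:-1], ex[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    genes: list[Gene]

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene_id in annotation")

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def tss_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "gene_start": [g.start for g in self.genes],
                "gene_end": [g.end for g in self.genes],
            }
        )


def read_gtf_lite(path) -> GenomeAnnotation:
    """Read a GTF-lite file (gene/exon features with a gene_id attribute).

    On-disk coordinates are 1-based closed and converted to internal
    0-based half-open (start-1, end).
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise BedParseError(f"{path}: line {lineno}: need 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            start, end = int(start1) - 1, int(end1)
            gene_id = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip('" ')
            if gene_id is None:
                raise BedParseError(f"{path}: line {lineno}: missing gene_id")
            if feature == "gene":
                genes[gene_id] = dict(
                    chrom=chrom, start=start, end=end, strand=strand
                )
            elif feature == "exon":
                exons.setdefault(gene_id, []).append((start, end))
    out = []
    for gene_id, info in genes.items():
        for (a, b) in exons.get(gene_id, []):
            if a < info["start"] or b > info["end"]:
                raise ValueError(f"exon outside gene body for gene_id {gene_id}")
        out.append(
            Gene(
                gene_id=gene_id,
                chrom=info["chrom"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                exons=sorted(exons.get(gene_id, [])),
            )
        )
    return GenomeAnnotation(out)


def write_gtf_lite(annotation: GenomeAnnotation, path) -> None:
    with _open_text(path, "wt") as fh:
        for g in annotation.genes:
            attr = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsmoltreg\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attr}\n"
            )
            for (a, b) in g.exons:
                fh.write(
                    f"{g.chrom}\tsmoltreg\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# Count matrices (TSV)
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    """Counts TSV: first column gene_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, week, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "week", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df.set_index("sample_id", drop=False)
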