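"""Genomic interval arithmetic, peak and gene-model I/O, and sequence retrieval.

Coordinates are 0-based half-open throughout (BED convention). Peaks carry a
summit — the base of maximal ChIP signal — which anchors every downstream
window, annotation and density computation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "PeakAnnotation",
    "read_peaks",
    "write_bed",
    "read_gene_models",
    "summit_window",
    "intersect",
    "annotate_peak",
    "annotate_peaks",
    "extract_sequences",
    "write_annotations",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
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
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    peak_id: str
    summit: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) for peak {self.peak_id}"
            )
        if self.score < 0:
            raise ValueError(f"score must be nonnegative, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    tss: int
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        expected_tss = self.span.start if self.strand == "+" else self.span.end - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"tss {self.tss} inconsistent with {self.strand} strand span "
                f"[{self.span.start}, {self.span.end}) for gene {self.gene_id}"
            )
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"exon {ex} outside span of gene {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.span.chrom


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    nearest_gene: str | None
    distance_to_tss: int | None
    feature: str  # promoter | exon | intron | intergenic


def _parse_int(token: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: {what} is not an integer: {token!r}") from None


def _parse_float(token: str, what: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: {what} is not numeric: {token!r}") from None


def read_peaks(path: str | os.PathLike, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from ``bed6``, ``narrowPeak`` or ``summit-bed`` files.

    narrowPeak column 10 is the 0-based summit offset from the interval start;
    an offset of -1 means "no summit called" and maps to the interval midpoint
    (floor). BED6 peaks likewise default to the midpoint. ``summit-bed`` is the
    MACS2 ``_summits.bed`` dialect: 1 bp intervals located at the summit.
    """
    if format not in ("bed6", "narrowPeak", "summit-bed"):
        raise ValueError(f"unknown peak format {format!r}")
    min_cols = {"bed6": 4, "narrowPeak": 10, "summit-bed": 4}[format]
    peaks: list[Peak] = []
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for "
                    f"{format}, got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], "start", path, lineno)
            end = _parse_int(cols[2], "end", path, lineno)
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"peak_{lineno}"
            score = _parse_float(cols[4], "score", path, lineno) if len(cols) > 4 else 0.0
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-", ".") else "."
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if format == "narrowPeak":
                offset = _parse_int(cols[9], "summit offset", path, lineno)
                if offset == -1:
                    summit = (start + end) // 2
                else:
                    if offset < 0:
                        raise ValueError(
                            f"{path}:{lineno}: summit offset must be >= 0 or -1, got {offset}"
                        )
                    summit = start + offset
                if not (start <= summit < end):
                    raise ValueError(
                        f"{path}:{lineno}: summit {summit} outside peak [{start}, {end})"
                    )
            elif format == "summit-bed":
                summit = start
            else:
                summit = (start + end) // 2
            peaks.append(Peak(interval, name, summit, score))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | os.PathLike) -> None:
    """Write peaks as canonical BED6 (integral scores printed as integers)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = int(p.score) if float(p.score).is_integer() else p.score
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.peak_id}\t{score}\t{p.interval.strand}\n"
            )


def read_gene_models(path: str | os.PathLike, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or the package's TSV gene table.

    TSV columns: gene_id, chrom, tss, strand, span_start, span_end,
    exon_blocks (``start-end`` pairs joined by commas; empty allowed).
    """
    path = os.fspath(path)
    genes: list[GeneModel] = []
    if format == "bed12":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 12:
                    raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name, strand = cols[3], cols[5]
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts = [int(x) for x in cols[11].rstrip(",").split(",")]
                if len(sizes) != len(starts) or len(sizes) != int(cols[9]):
                    raise ValueError(f"{path}:{lineno}: inconsistent block columns")
                span = GenomicInterval(chrom, start, end, strand)
                exons = tuple(
                    GenomicInterval(chrom, start + s, start + s + sz, strand)
                    for s, sz in zip(starts, sizes)
                )
                tss = start if strand == "+" else end - 1
                genes.append(GeneModel(name, tss, strand, span, exons))
    elif format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            required = {"gene_id", "chrom", "tss", "strand", "span_start", "span_end"}
            missing = required - idx.keys()
            if missing:
                raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
            for lineno, raw in enumerate(fh, start=2):
                line = raw.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                chrom = cols[idx["chrom"]]
                strand = cols[idx["strand"]]
                span = GenomicInterval(
                    chrom, int(cols[idx["span_start"]]), int(cols[idx["span_end"]]), strand
                )
                exons: tuple[GenomicInterval, ...] = ()
                if "exon_blocks" in idx and len(cols) > idx["exon_blocks"] and cols[idx["exon_blocks"]]:
                    exons = tuple(
                        GenomicInterval(chrom, int(b.split("-")[0]), int(b.split("-")[1]), strand)
                        for b in cols[idx["exon_blocks"]].split(",")
                    )
                genes.append(
                    GeneModel(cols[idx["gene_id"]], int(cols[idx["tss"]]), strand, span, exons)
                )
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return genes


def summit_window(
    peak: Peak,
    width: int = 150,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Interval of ``width`` bp centered on the peak summit.

    Clipped at position 0 always, and at the chromosome end when
    ``chrom_lengths`` supplies one. ``width`` must be even and positive.
    """
    if width <= 0 or width % 2:
        raise ValueError(f"width must be even and positive, got {width}")
    start = max(0, peak.summit - width // 2)
    end = peak.summit + width // 2
    if chrom_lengths is not None and peak.chrom in chrom_lengths:
        end = min(end, chrom_lengths[peak.chrom])
    return GenomicInterval(peak.chrom, start, end, peak.interval.strand)


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[int, int, int]]:
    """All pairs ``(a_index, b_index, overlap_bp)`` sharing >= min_overlap bases.

    Same-chromosome sweep; output sorted by ``a_index`` then ``b_index``.
    Half-open semantics: abutting intervals do not overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    out: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        candidates = by_chrom.get(iv.chrom)
        if not candidates:
            continue
        for s, e, j in candidates:
            if s >= iv.end:
                break
            ov = min(iv.end, e) - max(iv.start, s)
            if ov >= min_overlap:
                out.append((i, j, ov))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_margin: int = 1000,
) -> PeakAnnotation:
    """Assign the nearest-TSS gene and a genomic feature to one peak.

    The nearest gene minimizes |summit - tss| among genes on the peak's
    chromosome (ties to the lexicographically smaller gene_id). Distance is
    signed in gene orientation: negative = upstream of the TSS. Feature
    precedence at the summit position: promoter (|distance| strictly within
    the margin; a summit exactly ``promoter_margin`` bp away is distal) >
    exon > intron > intergenic; exon/intron membership considers every gene
    span on the chromosome, not only the nearest gene.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not same_chrom:
        return PeakAnnotation(peak.peak_id, None, None, "intergenic")
    s = peak.summit
    nearest = min(same_chrom, key=lambda g: (abs(s - g.tss), g.gene_id))
    distance = s - nearest.tss if nearest.strand == "+" else nearest.tss - s
    if abs(distance) < promoter_margin:
        feature = "promoter"
    else:
        in_span = [g for g in same_chrom if g.span.start <= s < g.span.end]
        if any(ex.start <= s < ex.end for g in in_span for ex in g.exons):
            feature = "exon"
        elif in_span:
            feature = "intron"
        else:
            feature = "intergenic"
    return PeakAnnotation(peak.peak_id, nearest.gene_id, distance, feature)


def annotate_peaks(
    peaks: Iterable[Peak],
    genes: Sequence[GeneModel],
    promoter_margin: int = 1000,
) -> list[PeakAnnotation]:
    return [annotate_peak(p, genes, promoter_margin) for p in peaks]


def _chrom_seq(genome, chrom: str) -> str | None:
    """Fetch a whole chromosome from a dict genome or a pyfaidx handle."""
    try:
        rec = genome[chrom]
    except KeyError:
        return None
    if isinstance(rec, str):
        return rec
    return str(rec[:])  # pyfaidx FastaRecord


def extract_sequences(genome, intervals: Sequence[GenomicInterval]) -> list[str]:
    """Extract uppercase sequences; minus-strand intervals reverse-complemented.

    ``genome`` is a ``dict[str, str]`` or a ``pyfaidx.Fasta`` handle. Missing
    chromosomes or out-of-bounds intervals raise with the offending interval
    named.
    """
    cache: dict[str, str | None] = {}
    out: list[str] = []
    for iv in intervals:
        if iv.chrom not in cache:
            cache[iv.chrom] = _chrom_seq(genome, iv.chrom)
        seq = cache[iv.chrom]
        if seq is None:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome ({iv})")
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(seq)}"
            )
        sub = seq[iv.start : iv.end].upper()
        out.append(reverse_complement(sub) if iv.strand == "-" else sub)
    return out


def write_annotations(annotations: Sequence[PeakAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tgene_id\tdistance_to_tss\tfeature\n")
        for a in annotations:
            gene = a.nearest_gene if a.nearest_gene is not None else "NA"
            dist = a.distance_to_tss if a.distance_to_tss is not None else "NA"
            fh.write(f"{a.peak_id}\t{gene}\t{dist}\t{a.feature}\n")
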