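"""Genome annotation model: chromosomes, ORFs, HM loci, ORC sites.

All coordinates are held internally as 0-based half-open intervals.
GFF3 input (1-based inclusive) and BED input (already 0-based half-open)
are converted on read, so downstream interval arithmetic never carries
off-by-one corrections.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


class LocationClass(str, Enum):
    """Genomic location category of an ORF.

    ``subtelomeric`` takes precedence over ``hm_proximal`` when both
    windows apply; every ORF receives exactly one class.
    """

    SUBTELOMERIC = "subtelomeric"
    HM_PROXIMAL = "hm_proximal"
    INTERIOR = "interior"


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(f"chromosome {self.name!r}: length must be >= 1")


@dataclass(frozen=True)
class OrfRecord:
    """One ORF as an unspliced genomic span, 0-based half-open."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"ORF {self.id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"ORF {self.id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return orf_center(self)


@dataclass(frozen=True)
class Interval:
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"invalid interval [{self.start}, {self.end})")


@dataclass
class GenomeAnnotation:
    chromosomes: list[Chromosome]
    orfs: list[OrfRecord]
    hm_loci: list[Interval] = field(default_factory=list)
    orc_sites: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise AnnotationError("duplicate chromosome names")
        ids = [o.id for o in self.orfs]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate ORF ids")
        lengths = self.chrom_lengths
        for orf in self.orfs:
            if orf.chromosome not in lengths:
                raise AnnotationError(
                    f"ORF {orf.id!r}: unknown chromosome {orf.chromosome!r}"
                )
            if orf.end > lengths[orf.chromosome]:
                raise AnnotationError(
                    f"ORF {orf.id!r}: end {orf.end} beyond chromosome "
                    f"{orf.chromosome!r} length {lengths[orf.chromosome]}"
                )
        for iv in list(self.hm_loci) + list(self.orc_sites):
            if iv.chromosome not in lengths:
                raise AnnotationError(f"interval on unknown chromosome {iv.chromosome!r}")
            if iv.end > lengths[iv.chromosome]:
                raise AnnotationError(
                    f"interval [{iv.start},{iv.end}) beyond chromosome "
                    f"{iv.chromosome!r} length {lengths[iv.chromosome]}"
                )
        self.orc_sites = merge_intervals(self.orc_sites)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def orc_sites_by_chromosome(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for site in self.orc_sites:
            out.setdefault(site.chromosome, []).append(site)
        for sites in out.values():
            sites.sort(key=lambda s: (s.start, s.end))
        return out


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended intervals per chromosome."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda s: (s.start, s.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a samtools .fai or a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise AnnotationError(f"{path}: need at least two columns (name, length)")
    lengths = {}
    for name, length in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)):
        if name in lengths:
            raise AnnotationError(f"{path}: duplicate chromosome {name!r}")
        lengths[name] = int(length)
    return lengths


def read_bed_intervals(path: str | Path, lengths: dict[str, int] | None = None) -> list[Interval]:
    """BED3+ intervals (0-based half-open), validated against lengths if given."""
    rows = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    out = []
    for chrom, start, end in rows.itertuples(index=False):
        chrom = str(chrom)
        if lengths is not None and chrom not in lengths:
            raise AnnotationError(f"{path}: unknown chromosome {chrom!r}")
        out.append(Interval(chrom, int(start), int(end)))
    return out


DEFAULT_ORF_TYPES = ("gene", "ORF", "CDS")


def read_annotation(
    gff: str | Path | io.TextIOBase,
    lengths: dict[str, int],
    hm_bed: str | Path | None = None,
    orc_bed: str | Path | None = None,
    feature_types: Sequence[str] = DEFAULT_ORF_TYPES,
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GFF3 + BED inputs.

    Only features whose type is in ``feature_types`` become ORF records.
    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    orfs: list[OrfRecord] = []
    seen_ids: set[str] = set()
    if isinstance(gff, (str, Path)):
        iterator = gffutils.iterators.DataIterator(str(gff))
    else:
        iterator = gffutils.iterators.DataIterator(gff.read(), from_string=True)
    for feat in iterator:
        if feat.featuretype not in feature_types:
            continue
        line = str(feat)
        if feat.seqid not in lengths:
            raise AnnotationError(f"unknown seqid {feat.seqid!r} in GFF line: {line}")
        if feat.end < feat.start:
            raise AnnotationError(f"end < start in GFF line: {line}")
        if feat.strand not in ("+", "-"):
            raise AnnotationError(f"missing or invalid strand in GFF line: {line}")
        attrs = feat.attributes
        fid = (attrs.get("ID") or attrs.get("Name") or [None])[0]
        if fid is None:
            fid = f"{feat.seqid}:{feat.start}-{feat.end}"
        if fid in seen_ids:
            raise AnnotationError(f"duplicate feature id {fid!r} in GFF line: {line}")
        seen_ids.add(fid)
        orfs.append(OrfRecord(fid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    chromosomes = [Chromosome(name, n) for name, n in lengths.items()]
    hm = read_bed_intervals(hm_bed, lengths) if hm_bed is not None else []
    orc = read_bed_intervals(orc_bed, lengths) if orc_bed is not None else []
    return GenomeAnnotation(chromosomes, orfs, hm_loci=hm, orc_sites=orc)


def write_gff3(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    """Write ORF records as GFF3 gene features (converts back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                f"{o.chromosome}\tsirscan\tgene\t{o.start + 1}\t{o.end}\t.\t"
                f"{o.strand}\t.\tID={o.id}\n"
            )


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\n")


def orf_center(orf: OrfRecord) -> int:
    """Center position of an ORF, floor((start + end) / 2), 0-based."""
    return (orf.start + orf.end) // 2


def _span_distance(start: int, end: int, other_start: int, other_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    if start < other_end and other_start < end:
        return 0
    if end <= other_start:
        return other_start - end
    return start - other_end


def classify_orf_location(
    orf: OrfRecord,
    annotation: GenomeAnnotation,
    telomere_window_bp: int = 20_000,
    hm_window_bp: int = 10_000,
) -> LocationClass:
    """Classify an ORF as subtelomeric, HM-proximal, or interior.

    Subtelomeric: ORF span within ``telomere_window_bp`` of either
    chromosome end. Otherwise HM-proximal: span within ``hm_window_bp``
    of any HM locus (overlap counts as distance 0). Subtelomeric wins
    when both apply.
    """
    if telomere_window_bp < 0 or hm_window_bp < 0:
        raise AnnotationError("location windows must be >= 0")
    lengths = annotation.chrom_lengths
    if orf.chromosome not in lengths:
        raise AnnotationError(f"ORF {orf.id!r}: chromosome {orf.chromosome!r} not in annotation")
    chrom_len = lengths[orf.chromosome]
    end_distance = min(orf.start, chrom_len - orf.end)
    if end_distance <= telomere_window_bp:
        return LocationClass.SUBTELOMERIC
    for hm in annotation.hm_loci:
        if hm.chromosome != orf.chromosome:
            continue
        if _span_distance(orf.start, orf.end, hm.start, hm.end) <= hm_window_bp:
            return LocationClass.HM_PROXIMAL
    return LocationClass.INTERIOR
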