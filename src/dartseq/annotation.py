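"""Transcript models, gene lookup and metagene coordinate mapping.

A :class:`TranscriptModel` holds the exon/CDS structure of one transcript and
maps between genomic, transcriptomic and metagene coordinates. The metagene
coordinate rescales the 5'UTR, CDS and 3'UTR each to one unit, so a coding
transcript spans [0, 3): [0,1) is the 5'UTR, [1,2) the CDS, [2,3) the 3'UTR,
measured 5'->3' on the transcript strand. The CDS start itself maps to exactly
1.0 and belongs to the CDS (half-open regions).

All genomic coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGION_NONCODING = "noncoding"
REGION_INTERGENIC = "intergenic"


class AnnotationError(ValueError):
    """Raised on structurally invalid annotation input."""


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are half-open genomic intervals, stored sorted and
    non-overlapping. ``cds_start``/``cds_end`` are genomic bounds of the
    coding region (half-open), both ``None`` for a noncoding transcript.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty or inverted exon [{s},{e})"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id}: partial CDS bounds"
            )
        if self.cds_start is not None:
            if self.cds_end <= self.cds_start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty CDS"
                )
            for bound in (self.cds_start, self.cds_end - 1):
                if not self._is_exonic(bound):
                    raise AnnotationError(
                        f"transcript {self.transcript_id}: CDS outside exons"
                    )

    # -- basic geometry ------------------------------------------------------

    def _is_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def exonic_positions(self) -> np.ndarray:
        """All exonic genomic positions, ascending."""
        return np.concatenate([np.arange(s, e) for s, e in self.exons])

    # -- coordinate mapping ---------------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int:
        """Transcript offset (0-based, 5'->3' on the transcript strand)."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus_offset = offset + (pos - s)
                if self.strand == "+":
                    return plus_offset
                return self.exonic_length - 1 - plus_offset
            offset += e - s
        raise AnnotationError(
            f"position {self.contig}:{pos + 1} is not exonic in {self.transcript_id}"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.exonic_length:
            raise AnnotationError(
                f"transcript coordinate {tpos} out of range for {self.transcript_id}"
            )
        plus_offset = tpos if self.strand == "+" else self.exonic_length - 1 - tpos
        for s, e in self.exons:
            if plus_offset < e - s:
                return s + plus_offset
            plus_offset -= e - s
        raise AssertionError("unreachable")

    # -- region lengths (transcript strand) -----------------------------------

    def _cds_transcript_bounds(self) -> tuple[int, int]:
        """CDS as a half-open interval in transcript coordinates."""
        if not self.is_coding:
            raise AnnotationError(f"transcript {self.transcript_id} is noncoding")
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end - 1)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    @property
    def utr5_length(self) -> int:
        return self._cds_transcript_bounds()[0]

    @property
    def cds_length(self) -> int:
        lo, hi = self._cds_transcript_bounds()
        return hi - lo

    @property
    def utr3_length(self) -> int:
        return self.exonic_length - self._cds_transcript_bounds()[1]

    def region_of(self, pos: int) -> str:
        """Region label for an exonic genomic position."""
        if not self.is_coding:
            return REGION_NONCODING
        t = self.genomic_to_transcript(pos)
        lo, hi = self._cds_transcript_bounds()
        if t < lo:
            return REGION_5UTR
        if t < hi:
            return REGION_CDS
        return REGION_3UTR


def to_meta_coordinate(t: TranscriptModel, pos: int) -> float:
    """Metagene coordinate in [0, 3) for an exonic position of a coding transcript.

    Each of 5'UTR, CDS and 3'UTR is linearly rescaled to one unit; the CDS
    start maps to exactly 1.0 and the 3'UTR start to exactly 2.0.
    """
    if not t.is_coding:
        raise AnnotationError(f"transcript {t.transcript_id} is noncoding")
    tpos = t.genomic_to_transcript(pos)
    lo, hi = t._cds_transcript_bounds()
    if tpos < lo:
        return tpos / lo
    if tpos < hi:
        return 1.0 + (tpos - lo) / (hi - lo)
    return 2.0 + (tpos - hi) / (t.exonic_length - hi)


def select_canonical(transcripts: Iterable[TranscriptModel]) -> TranscriptModel:
    """Pick one representative transcript per gene.

    Longest CDS wins; ties broken by longest exonic length, then by
    lexicographically smallest transcript_id. Noncoding transcripts have CDS
    length 0 for this purpose.
    """
    ts = list(transcripts)
    if not ts:
        raise AnnotationError("select_canonical on empty transcript set")
    return min(
        ts,
        key=lambda t: (
            -(t.cds_length if t.is_coding else 0),
            -t.exonic_length,
            t.transcript_id,
        ),
    )


@dataclass
class GeneIndex:
    """Position -> transcript/gene lookup over one annotation."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    canonical: dict[str, TranscriptModel] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    @classmethod
    def from_transcripts(cls, transcripts: Sequence[TranscriptModel]) -> "GeneIndex":
        index = cls()
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            if t.transcript_id in index.transcripts:
                raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
            index.transcripts[t.transcript_id] = t
            by_gene.setdefault(t.gene_id, []).append(t)
            s, e = t.span
            index._trees.setdefault(t.contig, IntervalTree()).addi(s, e, t.transcript_id)
        for gene_id, ts in by_gene.items():
            index.canonical[gene_id] = select_canonical(ts)
        return index

    def transcripts_at(self, contig: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.at(pos)]
        return sorted(hits, key=lambda t: t.transcript_id)

    def locate_site(self, contig: str, pos: int) -> tuple[str | None, str | None, str]:
        """(gene_id, strand, region) of a genomic position.

        The region is determined on the canonical transcript of the assigned
        gene. When several genes cover the position, a gene whose canonical
        transcript covers it exonically is preferred; remaining ties go to
        the smaller gene_id. Positions inside a gene span but not exonic on
        the canonical transcript are reported with gene and strand but region
        ``noncoding`` (introns are outside metagene space). Positions covered
        by no gene are intergenic and carry no strand.
        """
        genes = sorted({t.gene_id for t in self.transcripts_at(contig, pos)})
        exonic = [g for g in genes if self.canonical[g]._is_exonic(pos)]
        pool = exonic or genes
        if not pool:
            return None, None, REGION_INTERGENIC
        gene_id = min(pool)
        canon = self.canonical[gene_id]
        if canon._is_exonic(pos):
            return gene_id, canon.strand, canon.region_of(pos)
        return gene_id, canon.strand, REGION_NONCODING


# -- annotation parsing -------------------------------------------------------


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gtf(path: str) -> list[TranscriptModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF fields")
            contig, _, feature, start, end, _, strand, _, raw_attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(raw_attrs)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                raise AnnotationError(
                    f"{path}:{lineno}: {feature} feature without transcript_id"
                )
            interval = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            known = meta.setdefault(tid, (gid, contig, strand))
            if known != (gid, contig, strand):
                raise AnnotationError(f"{path}: inconsistent records for {tid}")
            (exons if feature == "exon" else cds).setdefault(tid, []).append(interval)
    models = []
    for tid, (gid, contig, strand) in meta.items():
        if tid not in exons:
            raise AnnotationError(f"{path}: transcript {tid} has CDS but no exons")
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        models.append(
            TranscriptModel(tid, gid, contig, strand, exons[tid], cds_start, cds_end)
        )
    return models


def _parse_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected 12 BED fields")
            contig, start, _end, name, _, strand = fields[:6]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: block count mismatch")
            offset = int(start)
            exons = [(offset + s, offset + s + z) for s, z in zip(starts, sizes)]
            coding = thick_end > thick_start
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    contig=contig,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                )
            )
    return models


def parse_annotation(path: str) -> GeneIndex:
    """Read a GTF (Ensembl-dialect attributes) or BED12 annotation."""
    if path.endswith((".bed", ".bed12")):
        models = _parse_bed12(path)
    else:
        models = _parse_gtf(path)
    return GeneIndex.from_transcripts(models)


def write_canonical_table(index: GeneIndex, path: str) -> None:
    """One row per gene: its canonical transcript and region lengths."""
    with open(path, "w") as fh:
        fh.write("#gene_id\ttranscript_id\tcontig\tstrand\tutr5\tcds\tutr3\texonic\n")
        for gene_id in sorted(index.canonical):
            t = index.canonical[gene_id]
            if t.is_coding:
                u5, cd, u3 = t.utr5_length, t.cds_length, t.utr3_length
            else:
                u5 = cd = u3 = 0
            fh.write(
                f"{gene_id}\t{t.transcript_id}\t{t.contig}\t{t.strand}\t"
                f"{u5}\t{cd}\t{u3}\t{t.exonic_length}\n"
            )
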