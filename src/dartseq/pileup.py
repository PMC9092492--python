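"""Per-position nucleotide counts from aligned reads.

The counts matrix is the substrate of edit-site calling: for every reference
position covered by at least one counted base we store how many reads carry
A, C, G or T there, in reference-plus-strand space. Strand resolution (which
of C>T / G>A is the biological C-to-U event) is deferred to the caller via
gene annotation.

Coordinates are 0-based half-open internally; the serialized matrix is
1-based (stated in the file header).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

DEFAULT_MIN_BASE_QUALITY = 25
DEFAULT_MIN_MAPPING_QUALITY = 10


class UnsortedInputError(ValueError):
    """Raised when alignments are not coordinate-sorted."""


class MatrixFormatError(ValueError):
    """Raised on a malformed serialized matrix line."""


@dataclass(frozen=True)
class PileupRecord:
    """Counts at one reference position (0-based ``pos``).

    ``coverage`` equals ``count_a + count_c + count_g + count_t``: bases below
    the quality threshold, Ns, deletions and reference skips are excluded
    from both the per-base counts and the coverage.
    """

    contig: str
    pos: int
    count_a: int
    count_c: int
    count_g: int
    count_t: int

    @property
    def coverage(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t

    def count(self, base: str) -> int:
        return (self.count_a, self.count_c, self.count_g, self.count_t)[_BASE_INDEX[base]]


@dataclass
class PileupMatrix:
    """Ordered per-contig, per-position nucleotide counts.

    Internally a mapping ``contig -> {pos -> int64[4]}``; iteration is always
    sorted by (contig, pos), so equal matrices serialize identically.
    """

    sample: str = ""
    replicate: int = 0
    condition: str = ""  # one of {"dart", "control", "deaminase_alone", ""}
    _data: dict[str, dict[int, np.ndarray]] = field(default_factory=dict, repr=False)

    # -- construction -------------------------------------------------------

    def add_base(self, contig: str, pos: int, base: str, n: int = 1) -> None:
        idx = _BASE_INDEX.get(base)
        if idx is None:
            return
        per_contig = self._data.setdefault(contig, {})
        counts = per_contig.get(pos)
        if counts is None:
            counts = np.zeros(4, dtype=np.int64)
            per_contig[pos] = counts
        counts[idx] += n

    def set_counts(self, contig: str, pos: int, counts: Iterable[int]) -> None:
        arr = np.asarray(list(counts), dtype=np.int64)
        if arr.shape != (4,) or (arr < 0).any():
            raise ValueError("counts must be four non-negative integers")
        if arr.any():
            self._data.setdefault(contig, {})[pos] = arr

    # -- access --------------------------------------------------------------

    def counts(self, contig: str, pos: int) -> np.ndarray | None:
        per_contig = self._data.get(contig)
        if per_contig is None:
            return None
        return per_contig.get(pos)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._data)

    def positions(self, contig: str) -> list[int]:
        return sorted(self._data.get(contig, ()))

    def records(self) -> Iterator[PileupRecord]:
        for contig in self.contigs:
            per_contig = self._data[contig]
            for pos in sorted(per_contig):
                a, c, g, t = (int(x) for x in per_contig[pos])
                yield PileupRecord(contig, pos, a, c, g, t)

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PileupMatrix):
            return NotImplemented
        if (self.sample, self.replicate, self.condition) != (
            other.sample,
            other.replicate,
            other.condition,
        ):
            return False
        return list(self.records()) == list(other.records())

    def total_coverage(self) -> int:
        return sum(int(v.sum()) for per in self._data.values() for v in per.values())


def build_pileup(
    alignments: str | pysam.AlignmentFile,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = DEFAULT_MIN_MAPPING_QUALITY,
    sample: str = "",
    replicate: int = 0,
    condition: str = "",
) -> PileupMatrix:
    """Count aligned read bases per reference position.

    Input must be coordinate-sorted SAM/BAM with duplicates already removed.
    CIGAR is handled per SAM semantics: M/=/X consume both query and
    reference, I consumes query only, D/N consume reference only and
    contribute no counts. Bases below ``min_base_quality``, reads below
    ``min_mapping_quality``, unmapped/secondary/supplementary records and
    non-ACGT bases are excluded.
    """
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    matrix = PileupMatrix(sample=sample, replicate=replicate, condition=condition)
    last: tuple[int, int] | None = None
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            key = (read.reference_id, read.reference_start)
            if last is not None and key < last:
                raise UnsortedInputError(
                    f"input not coordinate-sorted: read {read.query_name!r} at "
                    f"{read.reference_name}:{read.reference_start + 1} follows a "
                    "later position"
                )
            last = key
            if read.mapping_quality < min_mapping_quality:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            quals = read.query_qualities
            contig = read.reference_name
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                matrix.add_base(contig, rpos, seq[qpos].upper())
    finally:
        if own:
            af.close()
    return matrix


def pool_matrices(matrices: list[PileupMatrix]) -> PileupMatrix:
    """Element-wise sum of counts; positions present in any input appear."""
    if not matrices:
        raise ValueError("pool_matrices requires at least one matrix")
    pooled = PileupMatrix(
        sample="+".join(dict.fromkeys(m.sample for m in matrices if m.sample)) or "pooled",
        replicate=0,
        condition=matrices[0].condition,
    )
    for m in matrices:
        for contig, per_contig in m._data.items():
            dest = pooled._data.setdefault(contig, {})
            for pos, counts in per_contig.items():
                if pos in dest:
                    dest[pos] = dest[pos] + counts
                else:
                    dest[pos] = counts.copy()
    return pooled


_HEADER_COLS = ["contig", "pos", "A", "C", "G", "T", "coverage"]


def write_matrix(matrix: PileupMatrix, path: str) -> None:
    """Write tab-separated counts; pos is 1-based in the file."""
    with open(path, "w") as fh:
        fh.write("# dartseq pileup matrix; pos is 1-based; coverage = A+C+G+T\n")
        fh.write(
            f"# sample={matrix.sample} replicate={matrix.replicate} "
            f"condition={matrix.condition}\n"
        )
        fh.write("#" + "\t".join(_HEADER_COLS) + "\n")
        for rec in matrix.records():
            fh.write(
                f"{rec.contig}\t{rec.pos + 1}\t{rec.count_a}\t{rec.count_c}\t"
                f"{rec.count_g}\t{rec.count_t}\t{rec.coverage}\n"
            )


def read_matrix(path: str) -> PileupMatrix:
    matrix = PileupMatrix()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# sample="):
                    for token in line[2:].split():
                        key, _, value = token.partition("=")
                        if key == "sample":
                            matrix.sample = value
                        elif key == "replicate":
                            matrix.replicate = int(value)
                        elif key == "condition":
                            matrix.condition = value
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(fields)}"
                )
            try:
                contig = fields[0]
                pos = int(fields[1]) - 1
                counts = [int(x) for x in fields[2:6]]
                coverage = int(fields[6])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: {exc}") from exc
            if coverage != sum(counts):
                raise MatrixFormatError(
                    f"{path}:{lineno}: coverage {coverage} != sum of counts {sum(counts)}"
                )
            if matrix.counts(contig, pos) is not None:
                raise MatrixFormatError(f"{path}:{lineno}: duplicate position {contig}:{pos + 1}")
            matrix.set_counts(contig, pos, counts)
    return matrix
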