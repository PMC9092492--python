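"""Edit-site calling from sample vs. control pileup matrices.

A C-to-U (or A-to-I) edit site is called at an annotated, strand-resolvable
position when, in the DART sample, the position has at least ``min_coverage``
reads over the ref+alt pair, at least ``min_alt_reads`` edited reads, an edit
ratio within [``ratio_low``, ``ratio_high``] inclusive, and an edit ratio at
least ``min_fold`` times the control's ratio at the same position (a control
ratio of exactly zero passes — zero control editing is maximal enrichment).
The control must itself have ``min_control_coverage`` reads over the pair,
otherwise enrichment cannot be assessed and the position is not callable.

Ref/alt bases are strand-corrected: a C-to-U event on a minus-strand gene
appears as G>A in reference-plus-strand counts; A-to-I as A>G (plus) / T>C
(minus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .annotation import GeneIndex
from .pileup import PileupMatrix

C2U = "C2U"
A2I = "A2I"

#: (ref, alt) in reference-plus-strand space, by edit type and gene strand.
STRAND_BASES: dict[tuple[str, str], tuple[str, str]] = {
    (C2U, "+"): ("C", "T"),
    (C2U, "-"): ("G", "A"),
    (A2I, "+"): ("A", "G"),
    (A2I, "-"): ("T", "C"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the site-calling procedure.

    Defaults follow the standard deamination-based m6A pipeline: >=10 reads
    of coverage, edit ratio within 5-95% inclusive, >=1.2-fold enrichment
    over the control, >=2 edited reads, and sites found in only one replicate
    removed.
    """

    edit_type: str = C2U
    min_coverage: int = 10
    ratio_low: float = 0.05
    ratio_high: float = 0.95
    min_fold: float = 1.2
    min_alt_reads: int = 2
    min_control_coverage: int = 10
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if self.edit_type not in (C2U, A2I):
            raise CallerError(f"unknown edit_type {self.edit_type!r}")
        if not 0 <= self.ratio_low < self.ratio_high <= 1:
            raise CallerError("require 0 <= ratio_low < ratio_high <= 1")
        if self.min_fold < 1:
            raise CallerError("min_fold must be >= 1")
        if min(self.min_coverage, self.min_alt_reads, self.min_control_coverage) < 0:
            raise CallerError("count thresholds must be non-negative")


def compute_edit_ratio(n_ref: int, n_alt: int) -> float:
    """Fraction of edited reads among ref+alt reads at a position."""
    total = n_ref + n_alt
    if total <= 0:
        raise CallerError("edit ratio undefined: n_ref + n_alt == 0")
    return n_alt / total


@dataclass(frozen=True)
class EditSite:
    """One called editing event (``pos`` is 0-based internally)."""

    contig: str
    pos: int
    gene_strand: str
    edit_type: str
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    coverage: int
    edit_ratio: float
    control_ratio: float = 0.0
    fold_enrichment: float = math.inf
    gene_id: str | None = None
    region: str | None = None
    motif_context: str | None = None
    replicate_support: int = 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.gene_strand, self.edit_type)


class SiteSet:
    """Keyed collection of edit sites from one sample/condition.

    Keys are (contig, pos, strand, edit_type); iteration is in key order so
    equal sets serialize identically.
    """

    def __init__(
        self,
        sites: Iterable[EditSite] = (),
        params: CallerParams | None = None,
        sample: str = "",
        control_kind: str = "mut",
    ) -> None:
        self.params = params
        self.sample = sample
        self.control_kind = control_kind
        self._sites: dict[tuple, EditSite] = {}
        for site in sites:
            self.add(site)

    def add(self, site: EditSite) -> None:
        if site.key in self._sites:
            raise CallerError(f"duplicate site key {site.key}")
        self._sites[site.key] = site

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[EditSite]:
        for key in sorted(self._sites):
            yield self._sites[key]

    def __contains__(self, key: tuple) -> bool:
        return key in self._sites

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteSet):
            return NotImplemented
        return list(self) == list(other)

    def get(self, key: tuple) -> EditSite | None:
        return self._sites.get(key)

    def keys(self) -> set[tuple]:
        return set(self._sites)

    @property
    def edit_type(self) -> str | None:
        for site in self._sites.values():
            return site.edit_type
        return self.params.edit_type if self.params else None

    # -- serialization -------------------------------------------------------

    _TSV_COLS = (
        "contig pos strand ref alt n_ref n_alt coverage edit_ratio "
        "control_ratio fold gene region motif replicate_support"
    ).split()

    def to_tsv(self, path: str) -> None:
        """Site table, 1-based positions; '.' marks absent optional fields."""
        with open(path, "w") as fh:
            fh.write(f"# dartseq sites; pos is 1-based; edit_type={self.edit_type or '.'}\n")
            fh.write("#" + "\t".join(self._TSV_COLS) + "\n")
            for s in self:
                fold = "inf" if math.isinf(s.fold_enrichment) else repr(s.fold_enrichment)
                fh.write(
                    "\t".join(
                        [
                            s.contig,
                            str(s.pos + 1),
                            s.gene_strand,
                            s.ref_base,
                            s.alt_base,
                            str(s.n_ref),
                            str(s.n_alt),
                            str(s.coverage),
                            repr(s.edit_ratio),
                            repr(s.control_ratio),
                            fold,
                            s.gene_id if s.gene_id is not None else ".",
                            s.region if s.region is not None else ".",
                            s.motif_context if s.motif_context is not None else ".",
                            str(s.replicate_support),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str) -> "SiteSet":
        edit_type = None
        out = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if "edit_type=" in line:
                        value = line.split("edit_type=", 1)[1].strip()
                        edit_type = None if value == "." else value
                    continue
                f = line.split("\t")
                if len(f) != len(cls._TSV_COLS):
                    raise CallerError(
                        f"{path}:{lineno}: expected {len(cls._TSV_COLS)} fields, got {len(f)}"
                    )
                try:
                    site = EditSite(
                        contig=f[0],
                        pos=int(f[1]) - 1,
                        gene_strand=f[2],
                        edit_type=edit_type or _infer_edit_type(f[2], f[3], f[4]),
                        ref_base=f[3],
                        alt_base=f[4],
                        n_ref=int(f[5]),
                        n_alt=int(f[6]),
                        coverage=int(f[7]),
                        edit_ratio=float(f[8]),
                        control_ratio=float(f[9]),
                        fold_enrichment=float(f[10]),
                        gene_id=None if f[11] == "." else f[11],
                        region=None if f[12] == "." else f[12],
                        motif_context=None if f[13] == "." else f[13],
                        replicate_support=int(f[14]),
                    )
                except ValueError as exc:
                    raise CallerError(f"{path}:{lineno}: {exc}") from exc
                out.add(site)
        return out

    def to_bed(self, path: str) -> None:
        """BED6+ output, 0-based half-open; score = 1000 x edit ratio, rounded."""
        with open(path, "w") as fh:
            for s in self:
                name = f"{s.edit_type}|{s.gene_id or '.'}"
                score = round(1000 * s.edit_ratio)
                fh.write(
                    f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{name}\t{score}\t{s.gene_strand}\n"
                )


def _infer_edit_type(strand: str, ref: str, alt: str) -> str:
    for (etype, st), (r, a) in STRAND_BASES.items():
        if st == strand and (r, a) == (ref, alt):
            return etype
    raise CallerError(f"cannot infer edit type from strand={strand} {ref}>{alt}")


def call_sites_single(
    sample: PileupMatrix,
    control: PileupMatrix | None,
    index: GeneIndex,
    params: CallerParams,
    genome=None,
) -> SiteSet:
    """Call edit sites in one sample replicate against a (pooled) control.

    ``genome`` (a pyfaidx.Fasta or dict of sequences) is optional; when given,
    positions whose strand-corrected genomic reference base does not match
    the edit type's source base are skipped explicitly rather than relying on
    the ratio bounds to exclude them. ``control=None`` disables the control
    coverage and fold-enrichment checks (used e.g. when scanning
    deaminase-alone samples for blacklist positions).
    """
    if index is None:
        raise CallerError("an annotation index is required to resolve strands")
    if (
        control is not None
        and len(sample)
        and len(control)
        and not set(sample.contigs) & set(control.contigs)
    ):
        raise CallerError(
            "sample and control matrices share no contigs — different genomes?"
        )
    out = SiteSet(params=params, sample=sample.sample)
    for contig in sample.contigs:
        for pos in sample.positions(contig):
            gene_id, strand, region = index.locate_site(contig, pos)
            if strand is None:
                continue  # strand unknown -> ref/alt pair ambiguous
            ref_base, alt_base = STRAND_BASES[(params.edit_type, strand)]
            if genome is not None and _genome_base(genome, contig, pos) != ref_base:
                continue
            counts = sample.counts(contig, pos)
            n_ref = int(counts["ACGT".index(ref_base)])
            n_alt = int(counts["ACGT".index(alt_base)])
            pair = n_ref + n_alt
            if pair < params.min_coverage or n_alt < params.min_alt_reads:
                continue
            ratio = compute_edit_ratio(n_ref, n_alt)
            if not params.ratio_low <= ratio <= params.ratio_high:
                continue
            control_ratio = 0.0
            fold = math.inf
            if control is not None:
                ccounts = control.counts(contig, pos)
                if ccounts is None:
                    continue
                c_ref = int(ccounts["ACGT".index(ref_base)])
                c_alt = int(ccounts["ACGT".index(alt_base)])
                if c_ref + c_alt < params.min_control_coverage:
                    continue
                control_ratio = compute_edit_ratio(c_ref, c_alt)
                if control_ratio > 0:
                    fold = ratio / control_ratio
                    if ratio < params.min_fold * control_ratio:
                        continue
            out.add(
                EditSite(
                    contig=contig,
                    pos=pos,
                    gene_strand=strand,
                    edit_type=params.edit_type,
                    ref_base=ref_base,
                    alt_base=alt_base,
                    n_ref=n_ref,
                    n_alt=n_alt,
                    coverage=int(counts.sum()),
                    edit_ratio=ratio,
                    control_ratio=control_ratio,
                    fold_enrichment=fold,
                    gene_id=gene_id,
                    region=region,
                )
            )
    return out


def _genome_base(genome, contig: str, pos: int) -> str:
    if contig not in genome:
        raise CallerError(f"contig {contig!r} absent from genome")
    return str(genome[contig][pos : pos + 1]).upper()


def merge_replicates(per_replicate: list[SiteSet], min_replicates: int) -> SiteSet:
    """Keep sites found in at least ``min_replicates`` replicate sets.

    The merged site carries summed read counts over the supporting
    replicates, the arithmetic mean of their edit and control ratios, and
    the number of replicates the site was called in.
    """
    if not per_replicate:
        raise CallerError("merge_replicates requires at least one site set")
    edit_types = {s.edit_type for s in per_replicate if s.edit_type is not None}
    if len(edit_types) > 1:
        raise CallerError(f"heterogeneous edit types across replicates: {edit_types}")
    support: dict[tuple, list[EditSite]] = {}
    for siteset in per_replicate:
        for site in siteset:
            support.setdefault(site.key, []).append(site)
    merged = SiteSet(params=per_replicate[0].params)
    for key, sites in support.items():
        if len(sites) < min_replicates:
            continue
        mean_ratio = sum(s.edit_ratio for s in sites) / len(sites)
        mean_control = sum(s.control_ratio for s in sites) / len(sites)
        fold = mean_ratio / mean_control if mean_control > 0 else math.inf
        merged.add(
            replace(
                sites[0],
                n_ref=sum(s.n_ref for s in sites),
                n_alt=sum(s.n_alt for s in sites),
                coverage=sum(s.coverage for s in sites),
                edit_ratio=mean_ratio,
                control_ratio=mean_control,
                fold_enrichment=fold,
                replicate_support=len(sites),
            )
        )
    return merged
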