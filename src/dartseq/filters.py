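"""Post-calling site filters: RAC motif check and blacklist subtraction.

m6A is deposited in an RAC consensus (R = A/G, the central A methylated),
and the cytidine edited by the APOBEC1-YTH fusion is the C immediately 3' of
the methylated A. C-to-U mode therefore keeps only sites whose
transcript-strand trinucleotide ending at the edited base matches R-A-C.
A-to-I mode edits adenosines near, not adjacent to, m6A and must bypass the
motif filter entirely.

Blacklist subtraction removes positions edited by the deaminase alone
(no YTH targeting): any site whose key appears in any blacklist replicate
is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .caller import C2U, CallerError, SiteSet

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifNotApplicableError(CallerError):
    """Motif filtering requested for an edit type that has no motif."""


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def matches_iupac(seq: str, pattern: str) -> bool:
    """Exact-length IUPAC match; any base outside ACGT fails (conservative)."""
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq.upper(), pattern.upper()):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"unknown IUPAC code {code!r} in pattern")
        if base not in allowed:
            return False
    return True


@dataclass(frozen=True)
class MotifSpec:
    """IUPAC pattern anchored at the edited base.

    ``anchor`` is the index of the edited base within the pattern; the
    default RAC has the edited C at the final position (the methylated A is
    one base 5').
    """

    pattern: str = "RAC"
    anchor: int = 2

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        if not 0 <= self.anchor < len(self.pattern):
            raise ValueError("anchor must lie within the pattern")


def site_context(genome, contig: str, pos: int, strand: str, spec: MotifSpec) -> str | None:
    """Transcript-strand sequence context around one edited base.

    Returns ``None`` when the window would run off the contig. Minus-strand
    genes are evaluated on the reverse complement of the plus-strand genome.
    """
    if contig not in genome:
        raise CallerError(f"contig {contig!r} absent from genome")
    length = len(spec.pattern)
    if strand == "+":
        start = pos - spec.anchor
        end = start + length
    else:
        end = pos + spec.anchor + 1
        start = end - length
    if start < 0 or end > len(genome[contig]):
        return None
    window = str(genome[contig][start:end]).upper()
    return window if strand == "+" else reverse_complement(window)


def motif_filter(sites: SiteSet, genome, spec: MotifSpec | None = None) -> SiteSet:
    """Keep C-to-U sites whose transcript-strand context matches the motif.

    Contexts containing N (or falling off the contig) are removed —
    ambiguous sequence cannot confirm the consensus. A-to-I input is an
    error: that mode does not use a sequence consensus.
    """
    spec = spec or MotifSpec()
    if sites.edit_type is not None and sites.edit_type != C2U:
        raise MotifNotApplicableError(
            f"motif filter not applicable to edit type {sites.edit_type}"
        )
    out = SiteSet(params=sites.params, sample=sites.sample, control_kind=sites.control_kind)
    for site in sites:
        ctx = site_context(genome, site.contig, site.pos, site.gene_strand, spec)
        if ctx is None or not matches_iupac(ctx, spec.pattern):
            continue
        out.add(site)
    return out


def annotate_motifs(sites: SiteSet, genome, spec: MotifSpec | None = None) -> SiteSet:
    """Fill each site's ``motif_context`` with its transcript-strand window.

    Purely descriptive: no site is removed. Useful before writing the site
    table so the motif column is populated for any edit type.
    """
    spec = spec or MotifSpec()
    out = SiteSet(params=sites.params, sample=sites.sample, control_kind=sites.control_kind)
    for site in sites:
        ctx = site_context(genome, site.contig, site.pos, site.gene_strand, spec)
        out.add(replace(site, motif_context=ctx))
    return out


def blacklist_subtract(sites: SiteSet, blacklists: list[SiteSet]) -> SiteSet:
    """Remove sites whose key appears in ANY blacklist replicate.

    Matching is by exact key (contig, pos, strand, edit_type): the blacklist
    records editing *events*, i.e. positions, not genes.
    """
    banned: set[tuple] = set()
    for bl in blacklists:
        banned |= bl.keys()
    out = SiteSet(params=sites.params, sample=sites.sample, control_kind=sites.control_kind)
    for site in sites:
        if site.key not in banned:
            out.add(site)
    return out
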