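"""Site-set characterization: metagene profiles, distance to reference m6A
sites with an exon-shuffle null, edit-ratio distribution comparison, and
gene-set overlaps.

The metagene profile answers "where in the mRNA do sites fall" on the
standard 5'UTR/CDS/3'UTR axis; m6A is expected to pile up around the stop
codon and proximal 3'UTR. The distance histogram measures co-location with
an orthogonal reference site list (e.g. miCLIP single-nucleotide m6A calls);
the shuffle null re-places sites uniformly within the exons of their own
transcripts, destroying co-location while conserving per-transcript counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import GeneIndex, to_meta_coordinate
from .caller import CallerError, EditSite, SiteSet


# -- metagene ----------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Binned site density over the metagene axis [0, 3]."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_sites_used: int
    n_sites_skipped: int = 0

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metagene profile; n_sites_used={self.n_sites_used} "
                     f"n_sites_skipped={self.n_sites_skipped}\n")
            fh.write("#bin_start\tbin_end\tdensity\n")
            for lo, hi, d in zip(self.bin_edges[:-1], self.bin_edges[1:], self.density):
                fh.write(f"{lo:.6f}\t{hi:.6f}\t{d!r}\n")


def metagene_profile(
    sites: SiteSet, index: GeneIndex, bins_per_region: int = 50
) -> MetageneProfile:
    """Histogram of site metagene coordinates, one count per mappable site.

    A site is mappable when its gene's canonical transcript is coding and
    the site is exonic on it; other sites are tallied as skipped. Densities
    are normalized to sum to 1; with zero mappable sites they are NaN and
    ``n_sites_used`` is 0.
    """
    edges = np.linspace(0.0, 3.0, 3 * bins_per_region + 1)
    metas = []
    skipped = 0
    for site in sites:
        gene_id = site.gene_id
        if gene_id is None:
            gene_id, _, _ = index.locate_site(site.contig, site.pos)
        t = index.canonical.get(gene_id) if gene_id else None
        if t is None or not t.is_coding or not t._is_exonic(site.pos):
            skipped += 1
            continue
        metas.append(to_meta_coordinate(t, site.pos))
    if not metas:
        return MetageneProfile(edges, np.full(len(edges) - 1, np.nan), 0, skipped)
    counts, _ = np.histogram(metas, bins=edges)
    return MetageneProfile(edges, counts / counts.sum(), len(metas), skipped)


# -- distance to reference sites ---------------------------------------------


@dataclass
class DistanceHistogram:
    """Signed offsets from edit sites to their nearest reference site.

    Offsets are strand-aware: positive means the edit site lies 3' of the
    reference site on the transcript strand. Window half-width ``window``
    bounds the search; edit sites with no reference site within it are
    excluded and counted in ``n_excluded``.
    """

    window: int
    offsets: np.ndarray  # -window .. +window
    counts: np.ndarray
    n_sites_in_window: int
    n_excluded: int

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# distance histogram; window={self.window} "
                     f"n_in_window={self.n_sites_in_window} n_excluded={self.n_excluded}\n")
            fh.write("#offset\tcount\n")
            for off, c in zip(self.offsets, self.counts):
                fh.write(f"{off}\t{c}\n")


ReferenceSite = tuple[str, int, str]  # contig, 0-based pos, strand


def read_bed_sites(path: str, index: GeneIndex | None = None) -> list[ReferenceSite]:
    """Read reference sites from BED (>=3 columns; strand from column 6).

    Entries without a strand are resolved through the annotation index when
    one is given, else dropped.
    """
    out: list[ReferenceSite] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            contig, start = f[0], int(f[1])
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else None
            if strand is None and index is not None:
                _, strand, _ = index.locate_site(contig, start)
            if strand is None:
                continue
            out.append((contig, start, strand))
    return out


def distance_to_reference(
    sites: SiteSet,
    reference: Sequence[ReferenceSite],
    index: GeneIndex | None = None,
    window: int = 1000,
) -> DistanceHistogram:
    """Signed genomic offset of each edit site to the nearest same-strand
    reference site on the same contig, within +-window.

    Ties in absolute distance are broken toward the 5' (negative) offset so
    results are deterministic.
    """
    if window <= 0:
        raise CallerError("window must be positive")
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for contig, pos, strand in reference:
        by_key.setdefault((contig, strand), []).append(pos)  # type: ignore[arg-type]
    by_key = {k: np.asarray(sorted(v)) for k, v in by_key.items()}

    offsets = np.arange(-window, window + 1)
    counts = np.zeros(offsets.size, dtype=np.int64)
    n_in, n_excluded = 0, 0
    for site in sites:
        refs = by_key.get((site.contig, site.gene_strand))
        if refs is None or refs.size == 0:
            n_excluded += 1
            continue
        i = int(np.searchsorted(refs, site.pos))
        candidates = []
        if i < refs.size:
            candidates.append(int(refs[i]))
        if i > 0:
            candidates.append(int(refs[i - 1]))
        genomic = min(
            candidates,
            key=lambda r: (abs(site.pos - r), _signed(site.pos - r, site.gene_strand)),
        )
        delta = _signed(site.pos - genomic, site.gene_strand)
        if abs(delta) > window:
            n_excluded += 1
            continue
        counts[delta + window] += 1
        n_in += 1
    return DistanceHistogram(window, offsets, counts, n_in, n_excluded)


def _signed(genomic_delta: int, strand: str) -> int:
    return genomic_delta if strand == "+" else -genomic_delta


# -- exon shuffle null --------------------------------------------------------


def shuffle_sites(sites: SiteSet, index: GeneIndex, seed: int) -> SiteSet:
    """Re-place each transcript's sites uniformly over that transcript's
    exonic positions, without replacement.

    Per-transcript site counts are conserved; site attributes other than
    position travel with the site (motif context is cleared — it no longer
    describes the new position). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[EditSite]] = {}
    for site in sites:
        gene_id = site.gene_id
        if gene_id is None:
            gene_id, _, _ = index.locate_site(site.contig, site.pos)
        if gene_id is None or gene_id not in index.canonical:
            raise CallerError(
                f"site {site.contig}:{site.pos + 1} has no transcript to shuffle within"
            )
        groups.setdefault(gene_id, []).append(site)

    out = SiteSet(params=sites.params, sample=sites.sample, control_kind=sites.control_kind)
    for gene_id in sorted(groups):
        t = index.canonical[gene_id]
        pool = t.exonic_positions()
        group = groups[gene_id]
        if pool.size < len(group):
            raise CallerError(
                f"transcript {t.transcript_id}: fewer exonic positions than sites"
            )
        new_pos = rng.choice(pool, size=len(group), replace=False)
        for site, pos in zip(group, new_pos):
            out.add(
                replace(
                    site,
                    pos=int(pos),
                    region=t.region_of(int(pos)) if t.is_coding else site.region,
                    motif_context=None,
                )
            )
    return out


# -- edit-ratio distribution comparison ---------------------------------------


@dataclass
class RatioComparison:
    """Mann-Whitney U comparison of two edit-ratio samples, with ECDFs."""

    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    ecdf_a: tuple[np.ndarray, np.ndarray]  # sorted values, cumulative fraction
    ecdf_b: tuple[np.ndarray, np.ndarray]

    def ecdf_to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# U={self.u_statistic!r} p={self.p_value!r} method={self.method}\n")
            fh.write("#sample\tvalue\tcumulative_fraction\n")
            for label, (x, f) in (("a", self.ecdf_a), ("b", self.ecdf_b)):
                for xi, fi in zip(x, f):
                    fh.write(f"{label}\t{xi!r}\t{fi!r}\n")


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, x.size + 1) / x.size


def compare_ratio_distributions(a: Sequence[float], b: Sequence[float]) -> RatioComparison:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test with midrank ties.

    Small samples (min(n, m) <= 8, no ties) use the exact null distribution;
    otherwise the normal approximation with tie and continuity correction.
    Two identical samples give U = n*m/2 and p ~ 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CallerError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        if math.isnan(p):  # zero variance: every observation tied
            p = 1.0
    return RatioComparison(float(res.statistic), min(p, 1.0), method, _ecdf(x), _ecdf(y))


# -- gene-set overlap ---------------------------------------------------------


@dataclass
class GeneSetOverlap:
    consensus: set[str]
    pairwise: dict[tuple[str, str], int]
    set_sizes: dict[str, int]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# consensus size={len(self.consensus)}\n")
            fh.write("#set_a\tset_b\toverlap\n")
            for (na, nb), n in sorted(self.pairwise.items()):
                fh.write(f"{na}\t{nb}\t{n}\n")
            fh.write("#consensus genes\n")
            for g in sorted(self.consensus):
                fh.write(f"{g}\n")


def gene_set_overlap(
    sets: Mapping[str, Iterable[str]], min_support: int
) -> GeneSetOverlap:
    """Consensus gene list: genes present in >= min_support of the input sets.

    Gene identity is by case-normalized string match (upper-cased). Pairwise
    intersection counts support Venn-style reporting.
    """
    norm = {name: {str(g).upper() for g in genes} for name, genes in sets.items()}
    if not norm:
        raise CallerError("at least one gene set is required")
    if min_support > len(norm):
        raise CallerError(
            f"min_support {min_support} exceeds number of sets {len(norm)}"
        )
    tally: dict[str, int] = {}
    for genes in norm.values():
        for g in genes:
            tally[g] = tally.get(g, 0) + 1
    consensus = {g for g, n in tally.items() if n >= min_support}
    names = sorted(norm)
    pairwise = {
        (a, b): len(norm[a] & norm[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return GeneSetOverlap(consensus, pairwise, {n: len(s) for n, s in norm.items()})
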