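"""Ground-truth synthetic data: genome, annotation, pileups and alignments.

The generator emulates the statistical structure a deamination-based m6A
experiment produces, so every pipeline stage is testable without external
downloads:

* genes with 5'UTR/CDS/3'UTR structure and 1-3 exons on both strands;
* true methylation sites biased toward the 3'UTR, each with a per-site
  editing rate drawn from a Beta distribution (C-to-U truth sites sit in an
  RAC context on the transcript strand, the edited C one base 3' of the
  methylated A);
* negative-binomial coverage and binomial edited-read counts;
* a binding-deficient control that retains low-level residual editing at
  true sites (a fixed multiplier of each site's rate);
* low background off-target editing at every eligible base;
* deaminase-alone artifact positions, edited in the DART and
  deaminase-alone conditions, that only blacklist subtraction can remove.

All randomness flows from a single seed through named generator streams, so
outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneIndex, TranscriptModel
from .caller import C2U, STRAND_BASES
from .pileup import PileupMatrix

CONDITIONS = ("dart", "control", "deaminase_alone")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-experiment parameters.

    Defaults describe the standard scenario used throughout the test suite:
    200 true sites over 30 genes, mean editing rate ~0.3 (Beta(3,7)), a
    control retaining 10% of each site's rate, background editing 0.005,
    negative-binomial coverage with mean 50, and 3 replicates per condition.
    """

    edit_type: str = C2U
    n_genes: int = 30
    n_contigs: int = 2
    exons_per_gene: tuple[int, int] = (1, 3)
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 900)
    utr3_range: tuple[int, int] = (300, 900)
    intron_range: tuple[int, int] = (100, 400)
    intergenic_range: tuple[int, int] = (200, 500)
    n_true_sites: int = 200
    utr3_fraction: float = 0.6
    cds_fraction: float = 0.3  # remainder goes to the 5'UTR
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0
    dart_rate_alpha: float = 3.0
    dart_rate_beta: float = 7.0
    control_residual: float = 0.1
    background_rate: float = 0.005
    deaminase_rate: float = 0.3
    n_artifact_sites: int = 30
    n_replicates: int = 3
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.control_residual,
            self.background_rate,
            self.deaminase_rate,
            self.utr3_fraction,
            self.cds_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("rates and fractions must lie in [0, 1]")
        if self.utr3_fraction + self.cds_fraction > 1.0:
            raise SimulationError("region fractions exceed 1")
        if min(self.n_genes, self.n_replicates) < 1 or self.n_true_sites < 0:
            raise SimulationError("counts must be non-negative (>=1 gene/replicate)")


@dataclass(frozen=True)
class GroundTruthSite:
    """A simulated methylation site; ``pos`` is the EDITED base (0-based).

    For C-to-U truth the edited base is the cytidine one nucleotide 3' of
    the methylated adenosine, so its transcript-strand trinucleotide context
    is R-A-C by construction.
    """

    contig: str
    pos: int
    strand: str
    rate: float
    gene_id: str
    transcript_id: str
    region: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


@dataclass
class SimulatedReference:
    """In-memory genome + annotation + truth bundle."""

    config: SimConfig
    genome: dict[str, np.ndarray]  # contig -> byte array of ACGT codes
    transcripts: list[TranscriptModel]
    truth: list[GroundTruthSite]
    artifact_sites: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def index(self) -> GeneIndex:
        if not hasattr(self, "_index"):
            self._index = GeneIndex.from_transcripts(self.transcripts)
        return self._index

    def sequence(self, contig: str) -> str:
        return self.genome[contig].tobytes().decode()

    def sequences(self) -> dict[str, str]:
        return {c: self.sequence(c) for c in self.genome}


_BASE_CODES = np.frombuffer(b"ACGT", dtype="S1")


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASE_CODES[rng.integers(0, 4, size=n)].copy()


# -- gene/genome layout -------------------------------------------------------


def _split_lengths(rng: np.random.Generator, total: int, n_parts: int, min_part: int) -> list[int]:
    """Random composition of ``total`` into parts each >= min_part."""
    if n_parts * min_part > total:
        n_parts = max(1, total // min_part)
    cuts = np.sort(rng.integers(0, total - n_parts * min_part + 1, size=n_parts - 1))
    free = np.diff(np.concatenate([[0], cuts, [total - n_parts * min_part]]))
    return [int(f) + min_part for f in free]


def _layout_genes(cfg: SimConfig, rng: np.random.Generator):
    """Place genes sequentially along contigs; returns transcripts and contig lengths."""
    transcripts: list[TranscriptModel] = []
    contig_len = {f"chr{i + 1}": 0 for i in range(cfg.n_contigs)}
    contigs = list(contig_len)
    min_exon = max(80, cfg.read_length + 10)
    for g in range(cfg.n_genes):
        contig = contigs[g % cfg.n_contigs]
        strand = "+" if (g // cfg.n_contigs) % 2 == 0 else "-"
        u5 = int(rng.integers(*cfg.utr5_range, endpoint=True))
        cds = int(rng.integers(*cfg.cds_range, endpoint=True))
        u3 = int(rng.integers(*cfg.utr3_range, endpoint=True))
        exonic = u5 + cds + u3
        n_exons = int(rng.integers(*cfg.exons_per_gene, endpoint=True))
        exon_lens = _split_lengths(rng, exonic, n_exons, min_exon)
        cursor = contig_len[contig] + int(rng.integers(*cfg.intergenic_range, endpoint=True))
        exons = []
        for k, length in enumerate(exon_lens):
            if k:
                cursor += int(rng.integers(*cfg.intron_range, endpoint=True))
            exons.append((cursor, cursor + length))
            cursor += length
        contig_len[contig] = cursor
        gene_id = f"gene{g + 1:03d}"
        shell = TranscriptModel(f"tx{g + 1:03d}", gene_id, contig, strand, exons)
        # CDS occupies transcript coords [u5, u5+cds); convert to genomic bounds
        a = shell.transcript_to_genomic(u5)
        b = shell.transcript_to_genomic(u5 + cds - 1)
        transcripts.append(
            TranscriptModel(
                shell.transcript_id, gene_id, contig, strand, exons,
                cds_start=min(a, b), cds_end=max(a, b) + 1,
            )
        )
    tail = {c: n + 100 for c, n in contig_len.items()}
    return transcripts, tail


def _exon_transcript_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    """Each exon's half-open interval in transcript coordinates."""
    out = []
    offset = 0
    for s, e in t.exons:
        length = e - s
        if t.strand == "+":
            out.append((offset, offset + length))
        else:
            out.append((t.exonic_length - offset - length, t.exonic_length - offset))
        offset += length
    return out


def _region_bounds(t: TranscriptModel) -> dict[str, tuple[int, int]]:
    u5, cd = t.utr5_length, t.cds_length
    return {
        "5UTR": (0, u5),
        "CDS": (u5, u5 + cd),
        "3UTR": (u5 + cd, t.exonic_length),
    }


def _candidate_tcoords(t: TranscriptModel, region: str) -> list[int]:
    """Transcript coords in ``region`` whose 2-base-5' context stays within
    one exon (so genomic and spliced contexts coincide)."""
    lo, hi = _region_bounds(t)[region]
    out = []
    for es, ee in _exon_transcript_intervals(t):
        start = max(lo, es + 2)
        end = min(hi, ee)
        out.extend(range(start, end))
    return out


def simulate_reference(cfg: SimConfig) -> SimulatedReference:
    """Build genome, gene models and ground-truth sites for one experiment."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    transcripts, contig_len = _layout_genes(cfg, rng)
    genome = {c: _rand_seq(rng, n) for c, n in contig_len.items()}

    n3 = round(cfg.n_true_sites * cfg.utr3_fraction)
    ncds = round(cfg.n_true_sites * cfg.cds_fraction)
    per_region = {"3UTR": n3, "CDS": ncds, "5UTR": cfg.n_true_sites - n3 - ncds}

    truth: list[GroundTruthSite] = []
    chosen: dict[str, list[int]] = {t.transcript_id: [] for t in transcripts}
    for region, want in per_region.items():
        pool = [
            (t, tc) for t in transcripts for tc in _candidate_tcoords(t, region)
        ]
        rng.shuffle(pool)
        placed = 0
        for t, tc in pool:
            if placed == want:
                break
            taken = chosen[t.transcript_id]
            if any(abs(tc - prev) < 6 for prev in taken):
                continue
            taken.append(tc)
            rate = float(rng.beta(cfg.dart_rate_alpha, cfg.dart_rate_beta))
            pos = _plant_site(genome, t, tc, cfg.edit_type, rng)
            truth.append(
                GroundTruthSite(
                    t.contig, pos, t.strand, rate, t.gene_id, t.transcript_id,
                    region,
                )
            )
            placed += 1
        if placed < want:
            raise SimulationError(
                f"infeasible config: only {placed}/{want} sites fit in {region}"
            )

    ref = SimulatedReference(cfg, genome, transcripts, sorted(truth, key=lambda s: (s.contig, s.pos)))
    _pick_artifacts(ref, rng)
    return ref


def _plant_site(genome, t: TranscriptModel, tc: int, edit_type: str, rng) -> int:
    """Write the required sequence context into the genome; return the edited
    base's genomic position."""
    pos = t.transcript_to_genomic(tc)
    arr = genome[t.contig]
    if edit_type == C2U:
        # transcript-strand context R-A-C ending at the edited C
        r_code = b"A" if rng.integers(0, 2) == 0 else b"G"
        context = [r_code, b"A", b"C"]  # transcript strand, 5'->3'
        for offset, base in zip((-2, -1, 0), context):
            gpos = t.transcript_to_genomic(tc + offset)
            arr[gpos] = base if t.strand == "+" else base.decode().translate(_COMPLEMENT).encode()
    else:
        arr[pos] = b"A" if t.strand == "+" else b"T"
    return pos


def _pick_artifacts(ref: SimulatedReference, rng: np.random.Generator) -> None:
    cfg = ref.config
    source = STRAND_BASES[(cfg.edit_type, "+")][0]
    truth_keys = {s.key for s in ref.truth}
    pool = []
    for t in ref.transcripts:
        seq = ref.sequence(t.contig)
        want = source if t.strand == "+" else source.translate(_COMPLEMENT)
        for p in t.exonic_positions():
            p = int(p)
            if seq[p] == want and (t.contig, p, t.strand) not in truth_keys:
                pool.append((t.contig, p, t.strand))
    if len(pool) < cfg.n_artifact_sites:
        raise SimulationError("infeasible config: not enough eligible artifact positions")
    idx = rng.choice(len(pool), size=cfg.n_artifact_sites, replace=False)
    ref.artifact_sites = sorted(pool[i] for i in idx)


# -- rate model ---------------------------------------------------------------


def _position_rates(ref: SimulatedReference, condition: str):
    """Per-transcript arrays: exonic positions, plus-strand ref/alt bases,
    and the editing rate per position for ``condition``."""
    cfg = ref.config
    truth_rate = {s.key: s.rate for s in ref.truth}
    artifacts = set(ref.artifact_sites)
    source = STRAND_BASES[(cfg.edit_type, "+")][0]
    out = []
    for t in ref.transcripts:
        seq = ref.sequence(t.contig)
        want = source if t.strand == "+" else source.translate(_COMPLEMENT)
        positions = t.exonic_positions()
        rates = np.zeros(positions.size)
        eligible = np.zeros(positions.size, dtype=bool)
        for i, p in enumerate(positions):
            p = int(p)
            if seq[p] != want:
                continue
            eligible[i] = True
            rate = cfg.background_rate
            key = (t.contig, p, t.strand)
            site_rate = truth_rate.get(key)
            if site_rate is not None:
                if condition == "dart":
                    rate += site_rate
                elif condition == "control":
                    rate += cfg.control_residual * site_rate
            if key in artifacts and condition in ("dart", "deaminase_alone"):
                rate += cfg.deaminase_rate
            rates[i] = min(rate, 1.0)
        out.append((t, positions, eligible, rates))
    return out


def _condition_rng(cfg: SimConfig, condition: str, replicate: int, kind: int):
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 23, CONDITIONS.index(condition), replicate, kind])
    )


def simulate_pileups(
    ref: SimulatedReference, condition: str, replicate: int = 1
) -> PileupMatrix:
    """Draw one replicate's counts matrix for one condition.

    Coverage at every exonic position is negative-binomial; at eligible
    (source-base) positions the edited-read count is binomial in the
    condition's rate; all remaining reads carry the reference base.
    """
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    cfg = ref.config
    rng = _condition_rng(cfg, condition, replicate, 0)
    p = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    matrix = PileupMatrix(
        sample=f"{condition}_rep{replicate}", replicate=replicate, condition=condition
    )
    alt_plus = {  # plus-strand alt base by gene strand
        "+": STRAND_BASES[(cfg.edit_type, "+")][1],
        "-": STRAND_BASES[(cfg.edit_type, "-")][1],
    }
    for t, positions, eligible, rates in _position_rates(ref, condition):
        seq = ref.sequence(t.contig)
        coverage = rng.negative_binomial(cfg.coverage_dispersion, p, size=positions.size)
        alts = np.zeros(positions.size, dtype=np.int64)
        mask = eligible & (coverage > 0)
        alts[mask] = rng.binomial(coverage[mask], rates[mask])
        alt_base = alt_plus[t.strand]
        for pos, cov, alt in zip(positions, coverage, alts):
            if cov == 0:
                continue
            pos = int(pos)
            ref_base = seq[pos]
            counts = [0, 0, 0, 0]
            counts["ACGT".index(ref_base)] += int(cov - alt)
            if alt:
                counts["ACGT".index(alt_base)] += int(alt)
            matrix.set_counts(t.contig, pos, counts)
    return matrix


def simulate_all_pileups(ref: SimulatedReference) -> dict[str, list[PileupMatrix]]:
    """All replicates of all three conditions."""
    return {
        cond: [
            simulate_pileups(ref, cond, rep)
            for rep in range(1, ref.config.n_replicates + 1)
        ]
        for cond in CONDITIONS
    }


# -- read-level simulation ----------------------------------------------------


def simulate_alignments(
    ref: SimulatedReference,
    condition: str,
    path: str,
    replicate: int = 1,
    depth: float = 30.0,
) -> None:
    """Write a coordinate-sorted SAM of perfect-quality single-end reads.

    Reads are placed uniformly within single exons (no junction reads) at
    the requested mean depth; edited bases are injected per read with the
    same per-position rates as the counts model, so a pileup of the output
    reproduces the counts model's marginals in expectation.
    """
    cfg = ref.config
    rng = _condition_rng(cfg, condition, replicate, 1)
    L = cfg.read_length
    min_exon = min(e - s for t in ref.transcripts for s, e in t.exons)
    if L > min_exon:
        raise SimulationError(
            f"read length {L} exceeds the shortest exon ({min_exon} nt)"
        )
    rate_by_pos: dict[tuple[str, int], tuple[str, float]] = {}
    alt_plus = {
        "+": STRAND_BASES[(cfg.edit_type, "+")][1],
        "-": STRAND_BASES[(cfg.edit_type, "-")][1],
    }
    reads: list[tuple[str, int, str]] = []
    for t, positions, eligible, rates in _position_rates(ref, condition):
        seq = ref.sequence(t.contig)
        alt_base = alt_plus[t.strand]
        local = {
            int(p): r for p, e, r in zip(positions, eligible, rates) if e and r > 0
        }
        for s, e in t.exons:
            n_reads = math.ceil(depth * (e - s) / L)
            starts = rng.integers(s, e - L + 1, size=n_reads)
            for start in np.sort(starts):
                start = int(start)
                bases = list(seq[start : start + L])
                for p, r in local.items():
                    if start <= p < start + L and rng.random() < r:
                        bases[p - start] = alt_base
                reads.append((t.contig, start, "".join(bases)))
    reads.sort(key=lambda r: (list(ref.genome).index(r[0]), r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig, arr in ref.genome.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(arr)}\n")
        for i, (contig, start, bases) in enumerate(reads, start=1):
            fh.write(
                f"r{i:07d}\t0\t{contig}\t{start + 1}\t60\t{L}M\t*\t0\t0\t"
                f"{bases}\t{'I' * L}\n"
            )


# -- writers ------------------------------------------------------------------


def write_fasta(ref: SimulatedReference, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in ref.genome:
            fh.write(f">{contig}\n")
            seq = ref.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(ref: SimulatedReference, path: str) -> None:
    with open(path, "w") as fh:
        for t in ref.transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                for s, e in t.exons:
                    cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{t.contig}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def write_truth(ref: SimulatedReference, path: str) -> None:
    """Truth table TSV (pos 1-based, the edited base)."""
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tstrand\trate\tgene_id\ttranscript_id\tregion\n")
        for s in ref.truth:
            fh.write(
                f"{s.contig}\t{s.pos + 1}\t{s.strand}\t{s.rate!r}\t"
                f"{s.gene_id}\t{s.transcript_id}\t{s.region}\n"
            )


def read_truth(path: str) -> list[tuple[str, int, str]]:
    """(contig, 0-based pos, strand) keys from a truth table."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]) - 1, f[2]))
    return out


def simulate_dataset(cfg: SimConfig, out_dir: str, with_sam: bool = False) -> SimulatedReference:
    """Write a complete synthetic experiment to ``out_dir``.

    genome.fa, annotation.gtf, truth.tsv, and one matrix TSV per condition
    and replicate (``<condition>_rep<k>.matrix.tsv``); optionally SAM files.
    """
    from .pileup import write_matrix

    os.makedirs(out_dir, exist_ok=True)
    ref = simulate_reference(cfg)
    write_fasta(ref, os.path.join(out_dir, "genome.fa"))
    write_gtf(ref, os.path.join(out_dir, "annotation.gtf"))
    write_truth(ref, os.path.join(out_dir, "truth.tsv"))
    for cond in CONDITIONS:
        for rep in range(1, cfg.n_replicates + 1):
            m = simulate_pileups(ref, cond, rep)
            write_matrix(m, os.path.join(out_dir, f"{cond}_rep{rep}.matrix.tsv"))
            if with_sam:
                simulate_alignments(
                    ref, cond, os.path.join(out_dir, f"{cond}_rep{rep}.sam"), rep
                )
    return ref
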