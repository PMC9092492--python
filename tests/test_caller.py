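"""Edit-site calling: exact threshold semantics, brute-force oracle
equivalence on random matrices, self-null, monotonicity, strand symmetry,
replicate merging, and site-table serialization."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dartseq.caller import (
    A2I,
    C2U,
    STRAND_BASES,
    CallerError,
    CallerParams,
    EditSite,
    SiteSet,
    call_sites_single,
    compute_edit_ratio,
    merge_replicates,
)
from conftest import make_matrix


def brute_force_caller(sample, control, index, params):
    """Independent literal translation of the calling rules: walk every
    sample position and apply each threshold one by one."""
    called = {}
    for rec in sample.records():
        gene_id, strand, region = index.locate_site(rec.contig, rec.pos)
        if strand is None:
            continue
        ref_base, alt_base = STRAND_BASES[(params.edit_type, strand)]
        n_ref, n_alt = rec.count(ref_base), rec.count(alt_base)
        if n_ref + n_alt < params.min_coverage:
            continue
        if n_alt < params.min_alt_reads:
            continue
        ratio = n_alt / (n_ref + n_alt)
        if ratio < params.ratio_low or ratio > params.ratio_high:
            continue
        if control is not None:
            cc = control.counts(rec.contig, rec.pos)
            if cc is None:
                continue
            c_ref, c_alt = int(cc["ACGT".index(ref_base)]), int(cc["ACGT".index(alt_base)])
            if c_ref + c_alt < params.min_control_coverage:
                continue
            c_ratio = c_alt / (c_ref + c_alt)
            if c_ratio > 0 and ratio < params.min_fold * c_ratio:
                continue
        called[(rec.contig, rec.pos, strand)] = ratio
    return called


def random_matrix_pair(rng, contig="c", n_positions=400, span=10_000):
    """Counts concentrated near the calling thresholds so every rule is
    exercised: pair coverage around 8-14, alt counts 0-6, occasional
    control editing."""
    sample, control = {}, {}
    positions = rng.choice(span, size=n_positions, replace=False)
    for pos in positions:
        cov = int(rng.integers(5, 40))
        alt = int(rng.integers(0, 7))
        counts = [0, 0, 0, 0]
        ref_idx = int(rng.integers(0, 4))
        counts[ref_idx] = cov
        alt_idx = int(rng.integers(0, 4))
        if alt_idx != ref_idx:
            counts[alt_idx] = alt
        sample[(contig, int(pos))] = tuple(counts)
        if rng.random() < 0.9:  # 10% of positions lack control coverage
            c_cov = int(rng.integers(5, 40))
            c_alt = int(rng.integers(0, 4))
            c_counts = [0, 0, 0, 0]
            c_counts[ref_idx] = c_cov
            if alt_idx != ref_idx:
                c_counts[alt_idx] += c_alt
            control[(contig, int(pos))] = tuple(c_counts)
    return make_matrix(sample), make_matrix(control)


class TestEditRatio:
    @pytest.mark.parametrize("n_ref, n_alt, expected", [(8, 2, 0.20), (0, 5, 1.0)])
    def test_values(self, n_ref, n_alt, expected):
        assert compute_edit_ratio(n_ref, n_alt) == pytest.approx(expected)

    def test_zero_denominator_raises(self):
        with pytest.raises(CallerError):
            compute_edit_ratio(0, 0)


def call_one(sample_counts, control_counts, index, pos=500, **param_kwargs):
    """Call a single plus-strand CDS position; counts are (A, C, G, T)."""
    sample = make_matrix({("c", pos): sample_counts})
    control = make_matrix({("c", pos): control_counts}) if control_counts else None
    params = CallerParams(**param_kwargs)
    return call_sites_single(sample, control, index, params)


class TestThresholdSemantics:
    """The exact calling thresholds: >=10 reads, ratio within [0.05, 0.95],
    >=1.2-fold over control, >=2 edited reads."""

    CLEAN_CONTROL = (0, 50, 0, 0)  # C=50, zero editing

    def test_worked_example(self, two_gene_index):
        """Sample C=16,T=4 (ratio 0.20) vs control C=19,T=1 (0.05): called, fold 4."""
        sites = call_one((0, 16, 0, 4), (0, 19, 0, 1), two_gene_index)
        assert len(sites) == 1
        site = next(iter(sites))
        assert site.edit_ratio == pytest.approx(0.20)
        assert site.fold_enrichment == pytest.approx(4.0)
        assert (site.ref_base, site.alt_base) == ("C", "T")

    @pytest.mark.parametrize(
        "sample_counts, called, what",
        [
            ((0, 7, 0, 2), False, "pair coverage 9 fails"),
            ((0, 8, 0, 2), True, "pair coverage 10 passes"),
            ((0, 96, 0, 4), False, "ratio 0.04 fails"),
            ((0, 95, 0, 5), True, "ratio 0.05 passes"),
            ((0, 5, 0, 95), True, "ratio 0.95 passes"),
            ((0, 4, 0, 96), False, "ratio 0.96 fails"),
            ((0, 9, 0, 1), False, "1 alt read fails"),
            ((0, 8, 0, 2), True, "2 alt reads pass"),
        ],
    )
    def test_sample_side_thresholds(self, two_gene_index, sample_counts, called, what):
        sites = call_one(sample_counts, self.CLEAN_CONTROL, two_gene_index)
        assert (len(sites) == 1) == called, what

    @pytest.mark.parametrize(
        "sample_counts, control_counts, called, what",
        [
            # control ratio 0.5: sample 0.6 is exactly 1.2-fold -> pass
            ((0, 40, 0, 60), (0, 50, 0, 50), True, "fold 1.20 passes"),
            # sample 0.595 -> fold 1.19 -> fail
            ((0, 81, 0, 119), (0, 50, 0, 50), False, "fold 1.19 fails"),
            # control ratio 0.18 vs sample 0.20 -> fold ~1.11 -> fail
            ((0, 80, 0, 20), (0, 82, 0, 18), False, "fold 1.11 fails"),
            # zero control editing passes by convention
            ((0, 80, 0, 20), (0, 50, 0, 0), True, "control ratio 0 passes"),
            # control pair coverage 9 < 10 -> not callable
            ((0, 80, 0, 20), (0, 9, 0, 0), False, "thin control fails"),
        ],
    )
    def test_control_side_thresholds(
        self, two_gene_index, sample_counts, control_counts, called, what
    ):
        sites = call_one(sample_counts, control_counts, two_gene_index)
        assert (len(sites) == 1) == called, what

    def test_unannotated_position_not_callable(self, two_gene_index):
        sites = call_one((0, 16, 0, 4), self.CLEAN_CONTROL, two_gene_index, pos=1500)
        assert len(sites) == 0

    def test_genome_reference_check_skips_non_source_bases(self, two_gene_index):
        sample = make_matrix({("c", 500): (0, 16, 0, 4)})
        control = make_matrix({("c", 500): (0, 50, 0, 0)})
        genome = {"c": "T" * 3000}
        sites = call_sites_single(sample, control, two_gene_index, CallerParams(),
                                  genome=genome)
        assert len(sites) == 0


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_matrices(self, two_gene_index):
        """20 random 10 kb matrix pairs: identical output to the literal
        position-by-position filter."""
        # extend the gene index so most of the 10 kb span is annotated
        from dartseq.annotation import GeneIndex, TranscriptModel

        plus = TranscriptModel("txP", "gP", "c", "+", [(0, 5000)], 500, 4000)
        minus = TranscriptModel("txM", "gM", "c", "-", [(5200, 10000)], 5500, 9500)
        index = GeneIndex.from_transcripts([plus, minus])
        params = CallerParams()
        rng = np.random.default_rng(42)
        n_called_total = 0
        for _ in range(20):
            sample, control = random_matrix_pair(rng)
            mine = call_sites_single(sample, control, index, params)
            oracle = brute_force_caller(sample, control, index, params)
            got = {(s.contig, s.pos, s.gene_strand): s.edit_ratio for s in mine}
            assert got == oracle
            n_called_total += len(mine)
        assert n_called_total > 50  # the scenario actually produces calls

    def test_self_null(self, two_gene_index):
        """Calling any matrix against itself with min_fold > 1 yields nothing."""
        rng = np.random.default_rng(5)
        sample, _ = random_matrix_pair(rng, n_positions=300, span=3000)
        assert len(call_sites_single(sample, sample, two_gene_index, CallerParams())) == 0

    def test_threshold_monotonicity(self, two_gene_index):
        """Tightening any threshold never increases the number of calls."""
        rng = np.random.default_rng(6)
        sample, control = random_matrix_pair(rng, n_positions=300, span=3000)
        base = CallerParams()
        n0 = len(call_sites_single(sample, control, two_gene_index, base))
        from dataclasses import replace

        tighter = [
            replace(base, min_coverage=15),
            replace(base, min_alt_reads=4),
            replace(base, min_fold=2.0),
            replace(base, ratio_low=0.10, ratio_high=0.80),
        ]
        for params in tighter:
            assert len(call_sites_single(sample, control, two_gene_index, params)) <= n0


class TestStrandCorrectness:
    def test_minus_strand_gene_uses_g_to_a(self, two_gene_index):
        """The same C-to-U event appears as C>T on a plus gene and G>A on a
        minus gene; relabeling the strand swaps which counts pair is used."""
        from dartseq.annotation import GeneIndex, TranscriptModel

        counts = {("c", 500): (4, 16, 16, 4)}  # C>T ratio 0.2 and G>A ratio 0.2
        control = make_matrix({("c", 500): (0, 50, 50, 0)})
        for strand, (ref, alt) in (("+", ("C", "T")), ("-", ("G", "A"))):
            t = TranscriptModel("t", "g", "c", strand, [(0, 1000)], 200, 800)
            index = GeneIndex.from_transcripts([t])
            sites = call_sites_single(make_matrix(counts), control, index, CallerParams())
            assert len(sites) == 1
            site = next(iter(sites))
            assert (site.ref_base, site.alt_base) == (ref, alt)
            assert site.edit_ratio == pytest.approx(0.2)

    def test_a2i_base_pairs(self, two_gene_index):
        counts = make_matrix({("c", 500): (16, 0, 4, 0), ("c", 2500): (0, 4, 0, 16)})
        control = make_matrix({("c", 500): (50, 0, 0, 0), ("c", 2500): (0, 0, 0, 50)})
        sites = call_sites_single(counts, control, two_gene_index,
                                  CallerParams(edit_type=A2I))
        by_pos = {s.pos: s for s in sites}
        assert (by_pos[500].ref_base, by_pos[500].alt_base) == ("A", "G")
        assert (by_pos[2500].ref_base, by_pos[2500].alt_base) == ("T", "C")


def _site(pos, ratio, support=1):
    return EditSite(
        contig="c", pos=pos, gene_strand="+", edit_type=C2U, ref_base="C",
        alt_base="T", n_ref=int(round(20 * (1 - ratio))), n_alt=int(round(20 * ratio)),
        coverage=20, edit_ratio=ratio, replicate_support=support,
    )


class TestMergeReplicates:
    def test_site_in_one_of_three_removed(self):
        """{A,B}, {A}, {} with min 2 -> only A survives."""
        reps = [
            SiteSet([_site(1, 0.2), _site(2, 0.3)]),
            SiteSet([_site(1, 0.4)]),
            SiteSet([]),
        ]
        merged = merge_replicates(reps, 2)
        assert [s.pos for s in merged] == [1]
        assert next(iter(merged)).replicate_support == 2

    def test_intersection_semantics(self):
        """{A,B}, {B,C}, {B} with min 2 -> {B}."""
        reps = [
            SiteSet([_site(1, 0.2), _site(2, 0.2)]),
            SiteSet([_site(2, 0.2), _site(3, 0.2)]),
            SiteSet([_site(2, 0.2)]),
        ]
        merged = merge_replicates(reps, 2)
        assert [s.pos for s in merged] == [2]
        assert next(iter(merged)).replicate_support == 3

    def test_all_empty(self):
        assert len(merge_replicates([SiteSet(), SiteSet(), SiteSet()], 2)) == 0

    def test_mean_edit_ratio(self):
        merged = merge_replicates([SiteSet([_site(1, 0.2)]), SiteSet([_site(1, 0.4)])], 2)
        assert next(iter(merged)).edit_ratio == pytest.approx(0.3)

    def test_heterogeneous_edit_types_raise(self):
        a2i = EditSite("c", 1, "+", A2I, "A", "G", 16, 4, 20, 0.2)
        with pytest.raises(CallerError):
            merge_replicates([SiteSet([_site(1, 0.2)]), SiteSet([a2i])], 1)


class TestSiteSetSerialization:
    def test_tsv_roundtrip_random(self, tmp_path):
        rng = np.random.default_rng(11)
        sites = []
        for i in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            ref, alt = STRAND_BASES[(C2U, strand)]
            n_ref, n_alt = int(rng.integers(0, 100)), int(rng.integers(2, 50))
            sites.append(
                EditSite(
                    contig=f"chr{int(rng.integers(1, 4))}", pos=int(rng.integers(0, 10**6)),
                    gene_strand=strand, edit_type=C2U, ref_base=ref, alt_base=alt,
                    n_ref=n_ref, n_alt=n_alt, coverage=n_ref + n_alt + int(rng.integers(0, 5)),
                    edit_ratio=n_alt / (n_ref + n_alt),
                    control_ratio=float(rng.random() * 0.1),
                    fold_enrichment=math.inf if rng.random() < 0.3 else float(rng.random() * 10 + 1.2),
                    gene_id=None if rng.random() < 0.2 else f"g{i}",
                    region=str(rng.choice(["5UTR", "CDS", "3UTR"])),
                    motif_context=None if rng.random() < 0.5 else "GAC",
                    replicate_support=int(rng.integers(1, 4)),
                )
            )
        original = SiteSet(sites)
        path = str(tmp_path / "sites.tsv")
        original.to_tsv(path)
        assert SiteSet.from_tsv(path) == original

    def test_bed_scores_scaled_ratio(self, tmp_path):
        path = str(tmp_path / "sites.bed")
        SiteSet([_site(99, 0.25)]).to_bed(path)
        contig, start, end, name, score, strand = open(path).read().split()
        assert (contig, start, end, score, strand) == ("c", "99", "100", "250", "+")
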