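"""Shared fixtures: small hand-built annotations and the default synthetic
scenario (built once per session — several tests and the acceptance suite
measure different properties of the same simulated experiment)."""

from __future__ import annotations

import pytest

from dartseq import (
    CallerParams,
    GeneIndex,
    SimConfig,
    TranscriptModel,
    call_sites_single,
    merge_replicates,
    simulate_all_pileups,
    simulate_reference,
)
from dartseq.filters import blacklist_subtract, motif_filter
from dartseq.pileup import PileupMatrix, pool_matrices


@pytest.fixture(scope="session")
def default_ref():
    """The standard synthetic scenario: 200 truth sites, 30 genes, 3 reps."""
    return simulate_reference(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pileups(default_ref):
    return simulate_all_pileups(default_ref)


@pytest.fixture(scope="session")
def pipeline_result(default_ref, default_pileups):
    """Full pipeline on the default scenario: per-stage site sets + metrics."""
    ref = default_ref
    index = ref.index
    genome = ref.sequences()
    params = CallerParams()
    control = pool_matrices(default_pileups["control"])
    per_rep = [
        call_sites_single(m, control, index, params, genome=genome)
        for m in default_pileups["dart"]
    ]
    merged = merge_replicates(per_rep, params.min_replicates)
    rac = motif_filter(merged, genome)
    bl_params = CallerParams(ratio_high=1.0, min_fold=1.0)
    blacklists = [
        call_sites_single(m, None, index, bl_params, genome=genome)
        for m in default_pileups["deaminase_alone"]
    ]
    final = blacklist_subtract(rac, blacklists)
    truth_keys = {s.key for s in ref.truth}
    tp = sum(1 for s in final if (s.contig, s.pos, s.gene_strand) in truth_keys)
    return {
        "per_rep": per_rep,
        "merged": merged,
        "rac": rac,
        "final": final,
        "sensitivity": tp / len(ref.truth),
        "fdr": (len(final) - tp) / max(len(final), 1),
    }


def make_matrix(entries, **meta) -> PileupMatrix:
    """entries: {(contig, pos): (A, C, G, T)}"""
    m = PileupMatrix(**meta)
    for (contig, pos), counts in entries.items():
        m.set_counts(contig, pos, counts)
    return m


@pytest.fixture
def two_gene_index() -> GeneIndex:
    """One plus- and one minus-strand single-exon coding gene on contig 'c'.

    genePLUS: exon [0, 1000), CDS [200, 800)  (5'UTR 200, CDS 600, 3'UTR 200)
    geneMINUS: exon [2000, 3000), CDS [2200, 2800)
    """
    plus = TranscriptModel("txP", "genePLUS", "c", "+", [(0, 1000)], 200, 800)
    minus = TranscriptModel("txM", "geneMINUS", "c", "-", [(2000, 3000)], 2200, 2800)
    return GeneIndex.from_transcripts([plus, minus])


@pytest.fixture
def spliced_transcripts() -> dict[str, TranscriptModel]:
    """Coding transcripts with several exons, both strands, for coordinate tests.

    plus: exons [0,100)+[200,500), CDS [50,350)
      -> 5'UTR 50 nt, CDS 250 nt, 3'UTR 100 nt (exonic length 400)
    minus: exons [0,100)+[200,500), CDS [50,350), minus strand
      -> read 3'->5' genomically: 5'UTR 150 nt, CDS 250 nt... computed below
    """
    return {
        "plus": TranscriptModel("tp", "gp", "c1", "+", [(0, 100), (200, 500)], 50, 350),
        "minus": TranscriptModel("tm", "gm", "c1", "-", [(0, 100), (200, 500)], 50, 350),
    }
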