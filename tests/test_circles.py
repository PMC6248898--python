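"""Circle splice-junction classification, insert mapping and flank recovery."""

import numpy as np
import pytest

from retrosplice import (
    JunctionType,
    Reference,
    analyze_circle_read,
    classify_junction_read,
    map_insert,
    revcomp,
)
from retrosplice.io import Gene, SeqRead
from retrosplice.simulate import plant_site, random_seq


@pytest.fixture(scope="module")
def toy(ebs_wt):
    """Hand-assembled chromosome: two + genes (A carries a 10/11 and a 7/11
    site flanking a 60-nt fragment), one - gene, plus intergenic gaps."""
    rng = np.random.default_rng(20)
    gene_a = random_seq(rng, 300, 0.4)
    gene_a = plant_site(gene_a, 100, 10, ebs_wt, rng)  # fragment 5' flank site
    gene_a = plant_site(gene_a, 160, 7, ebs_wt, rng)  # fragment 3' flank site
    gene_b = random_seq(rng, 200, 0.4)
    gene_c = random_seq(rng, 150, 0.4)  # annotated on the minus strand
    gaps = [random_seq(rng, 30, 0.4) for _ in range(4)]
    chrom = gaps[0] + gene_a + gaps[1] + gene_b + gaps[2] + gene_c + gaps[3]
    a0 = len(gaps[0])
    b0 = a0 + 300 + len(gaps[1])
    c0 = b0 + 200 + len(gaps[2])
    ref = Reference(
        seqs={"chr1": chrom},
        genes=[
            Gene("geneA", "chr1", a0, a0 + 300, "+"),
            Gene("geneB", "chr1", b0, b0 + 200, "+"),
            Gene("geneC", "chr1", c0, c0 + 150, "-"),
        ],
    )
    intron = random_seq(rng, 200, 0.4)
    return ref, intron


def test_head_to_tail_read_is_perfect(toy):
    _, intron = toy
    call = classify_junction_read(intron[-30:] + intron[:30], intron)
    assert call.junction_type is JunctionType.perfect
    assert call.insert_len == 0


def test_linear_arrangement_is_unresolved(toy):
    _, intron = toy
    call = classify_junction_read(intron[:30] + intron[-30:], intron)
    assert call.junction_type is JunctionType.unresolved
    assert call.reason == "linear_arrangement"


def test_short_read_and_short_gap_are_unresolved(toy):
    _, intron = toy
    assert classify_junction_read("ACGU" * 5, intron).reason == "read_too_short"
    call = classify_junction_read(intron[-25:] + "ACGU" + intron[:25], intron)
    assert call.junction_type is JunctionType.unresolved
    assert call.reason == "insert_below_min"


def test_one_anchor_mismatch_tolerated_when_enabled(toy):
    _, intron = toy
    tail = intron[-30:]
    damaged = tail[:10] + ("A" if tail[10] != "A" else "C") + tail[11:]
    read = damaged + intron[:30]
    assert classify_junction_read(read, intron).junction_type is JunctionType.unresolved
    call = classify_junction_read(read, intron, max_mismatches=1)
    assert call.junction_type is JunctionType.perfect


def test_inserted_read_recovers_fragment_and_flank_scores(toy, ebs_wt):
    ref, intron = toy
    gene_a = ref.gene("geneA")
    frag = ref.transcript_seq(gene_a)[100:160]
    read = SeqRead("r1", intron[-30:] + frag + intron[:30])
    call = analyze_circle_read(read, intron, ref, ebs_wt)
    assert call.junction_type is JunctionType.inserted
    assert call.insert_len == 60 and call.insert_seq == frag
    assert call.origin.gene_id == "geneA"
    assert (call.origin.start, call.origin.end) == (gene_a.start + 100, gene_a.start + 160)
    assert call.origin.strand == "+"
    # the planted sites are recovered with their exact planted scores
    assert call.flank5_motif.score11 == 10
    assert call.flank3_motif.score11 == 7
    assert len(call.flank5) == 30 and len(call.flank3) == 30


def test_insert_spanning_two_genes_sets_intergenic_flag(toy):
    ref, _ = toy
    gene_a, gene_b = ref.gene("geneA"), ref.gene("geneB")
    insert = ref.seqs["chr1"][gene_a.end - 12 : gene_b.start + 13]
    origin = map_insert(insert, ref)
    assert origin is not None and origin.spans_intergenic
    assert origin.gene_id == "geneA;geneB"


def test_unmappable_insert_returns_none(toy):
    ref, _ = toy
    assert map_insert("A" * 15 + "C" * 15, ref) is None


def test_minus_strand_gene_maps_only_transcribed_strand(toy):
    ref, _ = toy
    gene_c = ref.gene("geneC")
    transcript = ref.transcript_seq(gene_c)
    origin = map_insert(transcript[40:80], ref)
    assert origin.gene_id == "geneC"
    assert origin.strand == "-"
    # genomic (non-transcribed) orientation must not be attributed to geneC
    genomic = ref.seqs["chr1"][gene_c.start + 40 : gene_c.start + 80]
    wrong = map_insert(genomic, ref)
    assert wrong is None or wrong.gene_id != "geneC"


def test_minus_strand_flanks_are_transcript_oriented(toy, ebs_wt):
    from retrosplice import extract_flanks

    ref, _ = toy
    gene_c = ref.gene("geneC")
    transcript = ref.transcript_seq(gene_c)
    origin = map_insert(transcript[40:80], ref)
    flank5, flank3, _, _ = extract_flanks(origin, ref, ebs_wt)
    assert flank5 == revcomp(ref.seqs["chr1"])[
        len(ref.seqs["chr1"]) - gene_c.end + 25 : len(ref.seqs["chr1"]) - gene_c.end + 55
    ]
    assert transcript[40:55] == flank5[15:]
    assert transcript[65:80] == flank3[:15]


def test_planted_circle_reads_roundtrip_through_caller(small_sim, ebs_wt):
    """Every generator circle read is classified with exact boundaries."""
    sim = small_sim
    by_read = {r.id: r for r in sim.reads}
    for ev in sim.manifest.events_of("perfect_circle"):
        for rid in ev.read_ids:
            call = analyze_circle_read(by_read[rid], sim.intron, sim.reference, ebs_wt)
            assert call.junction_type is JunctionType.perfect
    for ev in sim.manifest.events_of("inserted_circle"):
        for rid in ev.read_ids:
            call = analyze_circle_read(by_read[rid], sim.intron, sim.reference, ebs_wt)
            assert call.junction_type is JunctionType.inserted
            assert (call.origin.start, call.origin.end) == (
                ev.insert["chrom_start"], ev.insert["chrom_end"],
            )
            assert call.flank5_motif.score11 == ev.insert["flank5_score"]
            assert call.flank3_motif.score11 == ev.insert["flank3_score"]
            # the captured fragment sits downstream of the weaker invaded site
            assert call.flank3_motif.score11 <= call.flank5_motif.score11
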