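"""Both-strand CHR motif scanning and conservation filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chrscreen.conservation import ConservationTrack
from chrscreen.genome import GeneAnnotation, GeneModel
from chrscreen.motifs import CHR_MOTIFS, ChrMotifSet, DEFAULT_MOTIFS, reverse_complement
from chrscreen.scanner import (
    ConservedMotifHit,
    PromoterWindow,
    filter_conserved,
    gene_has_conserved_chr,
    scan_motifs,
)


def window_over(seq, gene_id="g", start=0):
    return PromoterWindow(
        gene_id=gene_id,
        chrom="chr1",
        tss=start,
        strand="+",
        interval=(start, start + len(seq)),
    )


def brute_force_hits(seq, start=0):
    """Independent oracle: try all 20 strings (10 motifs + reverse
    complements) at every offset of the uppercased sequence."""
    seq = seq.upper()
    hits = []
    for off in range(len(seq) - 5):
        word = seq[off : off + 6]
        for motif in CHR_MOTIFS:
            if word == motif:
                hits.append((start + off, "+", motif))
            if word == reverse_complement(motif):
                hits.append((start + off, "-", motif))
    return sorted(hits)


def as_tuples(hits):
    return sorted((h.start, h.hit_strand, h.motif) for h in hits)


def test_single_forward_occurrence():
    seq = "ACGACG" + "TTTGAA" + "CCGCCG"
    hits = scan_motifs(window_over(seq), seq)
    assert as_tuples(hits) == [(6, "+", "TTTGAA")]


def test_inverse_site_reported_as_minus_strand_canonical_motif():
    # TTCAAA is the functional inverse of the canonical CHR TTTGAA
    seq = "GGCGGC" + "TTCAAA" + "GGCGGC"
    hits = scan_motifs(window_over(seq), seq)
    assert as_tuples(hits) == [(6, "-", "TTTGAA")]


def test_palindromic_motif_reported_on_both_strands():
    # TTTAAA is its own reverse complement
    seq = "GCGCG" + "TTTAAA" + "GCGCG"
    hits = scan_motifs(window_over(seq), seq)
    assert as_tuples(hits) == [(5, "+", "TTTAAA"), (5, "-", "TTTAAA")]
    assert as_tuples(hits) == brute_force_hits(seq)


def test_overlapping_hits_all_reported():
    seq = "TTTTGAAA"  # TTTGAA at 1 (+); TTCAAA at 2 (- of TTTGAA)? verify by oracle
    hits = scan_motifs(window_over(seq), seq)
    assert as_tuples(hits) == brute_force_hits(seq)
    assert len(hits) >= 1


def test_lowercase_softmask_is_scanned():
    seq = "acgacg" + "tttgaa" + "ccgccg"
    hits = scan_motifs(window_over(seq), seq)
    assert as_tuples(hits) == [(6, "+", "TTTGAA")]


def test_n_positions_never_match():
    seq = "ACGACG" + "TTTGAN" + "CCGCCG"
    assert scan_motifs(window_over(seq), seq) == []


def test_sequence_shorter_than_window_fails():
    window = PromoterWindow(
        gene_id="g", chrom="chr1", tss=0, strand="+", interval=(0, 100)
    )
    with pytest.raises(ValueError, match="does not cover"):
        scan_motifs(window, "ACGT")


def test_genomic_coordinates_offset_by_window_start():
    chrom_seq = "A" * 500 + "TTTGAA" + "A" * 494
    window = PromoterWindow(
        gene_id="g", chrom="chr1", tss=500, strand="+", interval=(400, 700)
    )
    (hit,) = scan_motifs(window, chrom_seq)
    assert (hit.start, hit.end) == (500, 506)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_scanner_matches_brute_force_oracle_on_random_sequence(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    assert as_tuples(scan_motifs(window_over(seq), seq)) == brute_force_hits(seq)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_strand_symmetry_under_reverse_complement(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    mirrored = reverse_complement(seq)
    forward = as_tuples(scan_motifs(window_over(seq), seq))
    flipped = sorted(
        (len(seq) - h.end, {"+": "-", "-": "+"}[h.hit_strand], h.motif)
        for h in scan_motifs(window_over(mirrored), mirrored)
    )
    assert forward == flipped


def hit_at(start, gene_id="g"):
    return ConservedMotifHit(
        gene_id=gene_id,
        motif="TTTGAA",
        chrom="chr1",
        start=start,
        end=start + 6,
        hit_strand="+",
    )


def test_conservation_filter_boundary_is_inclusive():
    track = ConservationTrack(
        intervals={"chr1": [(0, 6, 0.9), (10, 16, 0.899), (20, 26, 1.0)]}
    )
    retained = filter_conserved([hit_at(0), hit_at(10), hit_at(20)], track)
    assert [h.start for h in retained] == [0, 20]
    assert retained[0].mean_conservation == pytest.approx(0.9)


def test_filter_empty_hit_list_is_identity():
    assert filter_conserved([], ConservationTrack()) == []


def test_raising_threshold_never_adds_hits():
    track = ConservationTrack(
        intervals={"chr1": [(i * 10, i * 10 + 6, s) for i, s in enumerate(
            [0.85, 0.9, 0.95, 1.0]
        )]}
    )
    hits = [hit_at(i * 10) for i in range(4)]
    previous = None
    for threshold in (0.8, 0.9, 0.95, 1.0):
        kept = {h.start for h in filter_conserved(hits, track, min_mean=threshold)}
        if previous is not None:
            assert kept <= previous
        previous = kept


def one_gene_setup(seq, cons_intervals):
    gene = GeneModel(
        gene_id="g",
        chrom="chr1",
        strand="+",
        tss_sites=(50,),
        gene_interval=(50, len(seq)),
    )
    annotation = GeneAnnotation(genes={"g": gene}, chrom_sizes={"chr1": len(seq)})
    track = ConservationTrack(intervals={"chr1": cons_intervals})
    return gene, annotation, track


def test_gene_passes_with_conserved_planted_motif():
    seq = "C" * 100 + "TTTGAA" + "C" * 100
    gene, annotation, track = one_gene_setup(seq, [(100, 106, 1.0)])
    has, best = gene_has_conserved_chr(gene, annotation, seq, track)
    assert has
    assert (best.start, best.motif, best.mean_conservation) == (100, "TTTGAA", 1.0)


def test_gene_fails_when_motif_below_conservation_threshold():
    seq = "C" * 100 + "TTCGAT" + "C" * 100
    gene, annotation, track = one_gene_setup(seq, [(100, 106, 0.5)])
    has, best = gene_has_conserved_chr(gene, annotation, seq, track)
    assert not has
    assert best is None


def test_best_hit_is_most_conserved_then_nearest_tss():
    seq = "C" * 20 + "TTTGAA" + "C" * 30 + "TTCGAA" + "C" * 50
    gene, annotation, track = one_gene_setup(
        seq, [(20, 26, 0.92), (56, 62, 0.95)]
    )
    has, best = gene_has_conserved_chr(gene, annotation, seq, track)
    assert has
    assert (best.start, best.motif) == (56, "TTCGAA")
    # equal conservation: the hit nearer the TSS (at 50) wins
    _, _, tied = one_gene_setup(seq, [(20, 26, 0.95), (56, 62, 0.95)])
    has, best = gene_has_conserved_chr(gene, annotation, seq, tied)
    assert best.start == 56


def test_custom_motif_set_from_file(tmp_path):
    path = tmp_path / "motifs.txt"
    path.write_text("# custom\nTTTGAA\nGCGCGC\n")
    motifs = ChrMotifSet.from_file(str(path))
    seq = "AATTAA" + "GCGCGC" + "AATTAA"
    hits = scan_motifs(window_over(seq), seq, motifs)
    assert {(h.start, h.motif) for h in hits} >= {(6, "GCGCGC")}


def test_default_motif_set_is_the_ten_variants():
    assert DEFAULT_MOTIFS.motifs == CHR_MOTIFS
    assert len(CHR_MOTIFS) == 10
    with pytest.raises(ValueError, match="duplicate"):
        ChrMotifSet(("TTTGAA", "TTTGAA"))
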