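import numpy as np
import pytest

from circkit.circ_annotate import CircRNARecord
from circkit.genome_annotation import GeneModel, GenomeSequence, reverse_complement
from circkit.junction_io import LinearJunction
from circkit.novel_discovery import (
    ACCEPTOR_WINDOW,
    DONOR_WINDOW,
    acceptor_window,
    characterize_exons,
    discover_novel_exons,
    donor_window,
    NovelExon,
    score_splice_site,
    train_splice_strength,
)


def _genome_with_exon(start=300, end=400, n=1000, seed=5, strand="+"):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bytearray(b"".join(bases[rng.integers(0, 4, size=n)]))
    if strand == "+":
        seq[start - 2 : start] = b"AG"
        seq[end : end + 2] = b"GT"
    else:
        seq[start - 2 : start] = b"AC"
        seq[end : end + 2] = b"CT"
    return GenomeSequence({"chr1": bytes(seq).decode()})


def _span_record(start=100, end=800, strand="+"):
    return CircRNARecord(
        chrom="chr1", start=start, end=end, strand=strand,
        gene_name="G", isoform_name="G.1", blocks=((start, end),),
        read_count=10, rpm=1.0, site_status=("annotated", "annotated"),
        circ_type="exonic", library_id="LIB1",
    )


def lj(start, end, strand="+"):
    return LinearJunction("chr1", start, end, 10, strand, "LIB1")


REF = GeneModel("G", "G.1", "chr1", "+", (100, 700), (200, 800))


class TestDiscoverNovelExons:
    def test_planted_exon_recovered(self):
        genome = _genome_with_exon(300, 400)
        junctions = [lj(200, 300), lj(400, 700)]
        exons = discover_novel_exons(
            [_span_record()], junctions, [REF], genome=genome
        )
        assert [(e.start, e.end) for e in exons] == [(300, 400)]

    def test_union_test_ensembl_only_exon_not_novel(self):
        # exon present in one reference source is not novel even if
        # absent from the others (union semantics)
        genome = _genome_with_exon(300, 400)
        ens = GeneModel("G", "G.ens", "chr1", "+", (100, 300, 700),
                        (200, 400, 800), source_tag="ensembl")
        refseq = GeneModel("G", "G.rs", "chr1", "+", (100, 700), (200, 800),
                           source_tag="refseq")
        junctions = [lj(200, 300), lj(400, 700)]
        exons = discover_novel_exons(
            [_span_record()], junctions, [ens, refseq], genome=genome
        )
        assert exons == []

    def test_missing_acceptor_motif_rejected(self):
        genome = _genome_with_exon(300, 400)
        # interval 310..400 has GT after 400 but no AG before 310
        junctions = [lj(200, 310), lj(400, 700)]
        exons = discover_novel_exons(
            [_span_record()], junctions, [REF], genome=genome
        )
        assert exons == []

    def test_minus_strand_motifs(self):
        genome = _genome_with_exon(300, 400, strand="-")
        ref = GeneModel("G", "G.1", "chr1", "-", (100, 700), (200, 800))
        junctions = [lj(200, 300, "-"), lj(400, 700, "-")]
        exons = discover_novel_exons(
            [_span_record(strand="-")], junctions, [ref], genome=genome
        )
        assert [(e.start, e.end, e.strand) for e in exons] == [(300, 400, "-")]

    def test_assembled_model_candidates(self):
        genome = _genome_with_exon(300, 400)
        asm = GeneModel("G", "G.asm", "chr1", "+", (300,), (400,),
                        source_tag="assembled")
        exons = discover_novel_exons(
            [_span_record()], [], [REF], assembled_models=[asm], genome=genome
        )
        assert [(e.start, e.end) for e in exons] == [(300, 400)]
        assert any(ev.startswith("assembled:") for ev in exons[0].evidence)

    def test_monotone_in_reference_union(self):
        genome = _genome_with_exon(300, 400)
        junctions = [lj(200, 300), lj(400, 700)]
        small_ref = [REF]
        big_ref = [
            REF,
            GeneModel("G", "G.2", "chr1", "+", (100, 300, 700),
                      (200, 400, 800), source_tag="known_genes"),
        ]
        found_small = discover_novel_exons(
            [_span_record()], junctions, small_ref, genome=genome
        )
        found_big = discover_novel_exons(
            [_span_record()], junctions, big_ref, genome=genome
        )
        assert {e.key for e in found_big} <= {e.key for e in found_small}

    def test_genome_required_for_motif_check(self):
        with pytest.raises(ValueError, match="genome"):
            discover_novel_exons([_span_record()], [], [REF], genome=None)


def _training_setup(n_genes=60, seed=2):
    """Genes with canonical motifs stamped at every splice site."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    models, pos = [], 0
    chrom_parts = []
    for gi in range(n_genes):
        pos += 100
        starts, ends = [], []
        for k in range(4):
            if k > 0:
                pos += 200
            starts.append(pos)
            pos += 100
            ends.append(pos)
        models.append(
            GeneModel(f"G{gi}", f"G{gi}.t1", "chr1", "+", tuple(starts), tuple(ends))
        )
    seq = bytearray(b"".join(bases[rng.integers(0, 4, size=pos + 100)]))
    for m in models:
        for gs, ge in m.introns:
            seq[gs : gs + 2] = b"GT"
            seq[ge - 2 : ge] = b"AG"
    return models, GenomeSequence({"chr1": bytes(seq).decode()})


class TestSpliceStrength:
    def test_window_sizes(self):
        models, genome = _training_setup()
        m = models[0]
        dw = donor_window(genome, "chr1", m.exon_ends[0], "+")
        aw = acceptor_window(genome, "chr1", m.exon_starts[1], "+")
        assert len(dw) == sum(DONOR_WINDOW) == 9
        assert len(aw) == sum(ACCEPTOR_WINDOW) == 23
        assert dw[3:5] == "GT"  # intron positions +1,+2
        assert aw[18:20] == "AG"

    def test_consensus_scores_maximally(self):
        models, genome = _training_setup()
        sm = train_splice_strength(models, genome, min_sites=100)
        cons = sm.consensus("donor")
        best = score_splice_site(sm, cons, "donor")
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = "".join(rng.choice(list("ACGT"), size=9))
            assert score_splice_site(sm, w, "donor") <= best + 1e-9

    def test_random_windows_score_below_consensus(self):
        # [DERIVED] Monte-Carlo over 1000 seeded random windows
        models, genome = _training_setup()
        sm = train_splice_strength(models, genome, min_sites=100)
        best = score_splice_site(sm, sm.consensus("acceptor"), "acceptor")
        rng = np.random.default_rng(1)
        scores = [
            score_splice_site(
                sm, "".join(rng.choice(list("ACGT"), size=23)), "acceptor"
            )
            for _ in range(1000)
        ]
        assert np.mean(scores) < best

    def test_gt_less_window_penalized_not_rejected(self):
        models, genome = _training_setup()
        sm = train_splice_strength(models, genome, min_sites=100)
        w_gt = "AAA" + "GT" + "AAAA"
        w_cc = "AAA" + "CC" + "AAAA"
        s_gt = score_splice_site(sm, w_gt, "donor")
        s_cc = score_splice_site(sm, w_cc, "donor")
        assert np.isfinite(s_cc) and s_cc < s_gt

    def test_wrong_length_error(self):
        models, genome = _training_setup()
        sm = train_splice_strength(models, genome, min_sites=100)
        with pytest.raises(ValueError, match="9 nt"):
            score_splice_site(sm, "ACGT", "donor")

    def test_too_few_training_sites(self):
        models, genome = _training_setup(n_genes=5)
        with pytest.raises(ValueError, match="training"):
            train_splice_strength(models, genome, min_sites=200)

    def test_strand_symmetric_windows(self):
        # a minus-strand site scored on the reverse complement equals the
        # mirrored plus-strand construction
        models, genome = _training_setup()
        m = models[0]
        donor = m.exon_ends[0]
        plus_w = donor_window(genome, "chr1", donor, "+")
        # build the mirrored genome: reverse complement of the chromosome
        n = genome.lengths["chr1"]
        rc_genome = GenomeSequence(
            {"chr1": reverse_complement(genome.slice("chr1", 0, n))}
        )
        minus_w = donor_window(rc_genome, "chr1", n - donor, "-")
        assert minus_w == plus_w

    def test_consensus_beats_its_reverse_complement(self):
        models, genome = _training_setup()
        sm = train_splice_strength(models, genome, min_sites=100)
        for kind in ("donor", "acceptor"):
            cons = sm.consensus(kind)
            assert score_splice_site(sm, cons, kind) >= score_splice_site(
                sm, reverse_complement(cons), kind
            )


class TestCharacterizeExons:
    def _exon(self, chrom_seq, start, end):
        genome = GenomeSequence({"chr1": chrom_seq})
        ex = NovelExon("chr1", start, end, "+", "G", ("junctions:x",))
        models, train_genome = _training_setup()
        sm = train_splice_strength(models, train_genome, min_sites=100)
        return genome, ex, sm

    def test_gc_extremes(self):
        pad = "A" * 50
        genome, ex, sm = self._exon(pad + "GGCC" + pad, 50, 54)
        (row,) = characterize_exons([ex], genome, sm)
        assert row["gc_fraction"] == 1.0
        genome, ex, sm = self._exon(pad + "ATAT" + pad, 50, 54)
        (row,) = characterize_exons([ex], genome, sm)
        assert row["gc_fraction"] == 0.0

    def test_all_n_exon_flagged(self):
        pad = "A" * 50
        genome, ex, sm = self._exon(pad + "NNNN" + pad, 50, 54)
        (row,) = characterize_exons([ex], genome, sm)
        assert row["gc_fraction"] is None

    def test_ese_density_planted_motifs(self):
        # [DERIVED] 5 planted hexamers in a 1000-nt A-background
        motif = "GAAGAA"
        seq = list("A" * 1100)
        for pos in (60, 200, 400, 600, 990):
            seq[pos : pos + 6] = motif
        genome, ex, sm = self._exon("".join(seq), 50, 1050)
        (row,) = characterize_exons([ex], genome, sm, ese_motifs=[motif])
        assert row["ese_density_per_kb"] == pytest.approx(5.0)

    def test_overlapping_motifs_counted(self):
        seq = "A" * 50 + "GGGGG" + "A" * 50
        genome, ex, sm = self._exon(seq, 50, 55)
        (row,) = characterize_exons([ex], genome, sm, ese_motifs=["GGGG"])
        # GGGGG contains two overlapping GGGG matches in 5 nt
        assert row["ese_density_per_kb"] == pytest.approx(2 * 1000 / 5)
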