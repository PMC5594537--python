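import numpy as np
import pytest
from Bio import Align

from oryzamir.formats import FeatureRecord, GenomeRecord, revcomp
from oryzamir.homology import (
    FilterThresholds,
    GenomeIndex,
    Hit,
    PrecursorQuery,
    ScoringScheme,
    classify_context,
    criterion_length,
    criterion_mature_mismatch,
    evaluate_candidate,
    evaluate_candidate as _eval,
    group_paralogues,
    scan_te_overlap,
    search_homologs,
)


def make_query(rng, loop="AACAAUAACAACACA"):
    """A hairpin-forming query precursor with an annotated mature."""
    from oryzamir.simulate import SimulationConfig, build_ancestor

    cfg = SimulationConfig(loop_len=len(loop))
    prec = build_ancestor(rng, cfg)
    return PrecursorQuery(
        id="q1", family="f1", sequence=prec.seq,
        mature_interval=prec.mature, star_interval=prec.star,
    )


def random_genome(rng, n, name="chr1"):
    return GenomeRecord(name, "".join(rng.choice(list("ACGT"), size=n)))


def biopython_local_score(query: str, subject: str, sc: ScoringScheme) -> float:
    """Independent local-alignment oracle (exhaustive Smith-Waterman)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = sc.match
    aligner.mismatch_score = sc.mismatch
    # our convention: a gap of length k costs open + k * extend
    aligner.open_gap_score = -(sc.gap_open + sc.gap_extend)
    aligner.extend_gap_score = -sc.gap_extend
    return aligner.score(query, subject)


class TestScoringScheme:
    def test_lambda_satisfies_karlin_altschul_identity(self):
        sc = ScoringScheme()
        p = 0.25
        total = 4 * p * p * np.exp(sc.lambda_ * sc.match) + 12 * p * p * np.exp(
            sc.lambda_ * sc.mismatch
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_evalue_monotonically_decreases_with_score(self):
        sc = ScoringScheme()
        scores = np.arange(12, 60)
        es = [sc.evalue(s, 100, 1_000_000) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1.0, mismatch=-2.0)


class TestSearch:
    def test_planted_query_found_exactly(self, rng):
        q = make_query(rng)
        bg = random_genome(rng, 4000).sequence
        genome = [GenomeRecord("chr1", bg[:2000] + q.sequence + bg[2000:])]
        hits = search_homologs(q, genome)
        assert hits
        top = hits[0]
        assert (top.start, top.end) == (2000, 2000 + len(q.sequence))
        assert top.identity == 1.0
        assert top.e_value < 1e-10

    def test_minus_strand_hit_reported_on_genome_coordinates(self, rng):
        q = make_query(rng)
        bg = random_genome(rng, 3000).sequence
        genome = [GenomeRecord("chr1", bg[:1000] + revcomp(q.sequence) + bg[1000:])]
        hits = search_homologs(q, genome)
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (1000, 1000 + len(q.sequence))

    def test_strand_symmetry(self, rng):
        q = make_query(rng)
        bg = random_genome(rng, 3000).sequence
        seq = bg[:1500] + q.sequence + bg[1500:]
        fwd = search_homologs(q, [GenomeRecord("chr1", seq)])
        rev = search_homologs(q, [GenomeRecord("chr1", revcomp(seq))])
        n = len(seq)
        mirrored = sorted((n - h.end, n - h.start, h.raw_score) for h in rev)
        assert sorted((h.start, h.end, h.raw_score) for h in fwd) == mirrored

    def test_reversed_but_not_complemented_query_not_found(self, rng):
        q = make_query(rng)
        bg = random_genome(rng, 3000).sequence
        genome = [GenomeRecord("chr1", bg[:1000] + q.sequence[::-1] + bg[1000:])]
        hits = search_homologs(q, genome)
        spans = [(h.start, h.end) for h in hits]
        # the reversed copy itself must not yield an accepted span
        assert not any(s < 1000 + len(q.sequence) and 1000 < e for s, e in spans)

    def test_score_equals_exhaustive_smith_waterman(self, rng):
        sc = ScoringScheme()
        for trial in range(5):
            q = make_query(rng)
            bg = random_genome(rng, 2000).sequence
            pos = int(rng.integers(0, 1800))
            mutated = list(q.sequence)
            for _ in range(6):  # a diverged homolog
                i = int(rng.integers(len(mutated)))
                mutated[i] = "ACGT"[int(rng.integers(4))]
            subject = bg[:pos] + "".join(mutated) + bg[pos:]
            hits = search_homologs(q, [GenomeRecord("chr1", subject)], scoring=sc)
            oracle = max(
                biopython_local_score(q.sequence, subject, sc),
                biopython_local_score(q.sequence, revcomp(subject), sc),
            )
            assert hits[0].raw_score == pytest.approx(oracle)

    def test_query_shorter_than_word_size_rejected(self):
        q = PrecursorQuery.__new__(PrecursorQuery)
        q.id, q.family, q.sequence = "q", "f", "ACGTACG"
        q.mature_interval, q.star_interval = (0, 7), None
        with pytest.raises(ValueError, match="word size"):
            search_homologs(q, [GenomeRecord("c", "ACGT" * 100)])


class TestCriteria:
    def _hit(self, span, qlen=100):
        return Hit(
            query_id="q", chrom="c", strand="+", start=0, end=span,
            raw_score=1, bit_score=1, e_value=0, aligned_query="", aligned_subject="",
            identity=1.0,
        )

    @pytest.mark.parametrize("span,expected", [(80, True), (79, False), (120, True)])
    def test_length_criterion_boundary(self, span, expected):
        q = PrecursorQuery(
            id="q", family="f", sequence="A" * 100, mature_interval=(0, 21)
        )
        assert criterion_length(self._hit(span), q) is expected

    @pytest.mark.parametrize(
        "cand,query,expected",
        [
            ("ACGTACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGTA", 0),
            ("ACGTACGTACGTACGTACGTA", "TCGTACGTACGTACGTACGTC", 2),
            ("ACGTACGTACGTACGTACGTA", "TCGTACGTACGTACGTACGAC", 3),
            # one substitution plus one 1-nt gap = 2 mismatch columns
            ("ACGTACGTACGTACGTACGT", "CCGTACGTACGTACGTACGTA", 2),
        ],
    )
    def test_mature_mismatch_counts_substitutions_and_indels(self, cand, query, expected):
        assert criterion_mature_mismatch(cand, query) == expected


class TestEvaluate:
    def test_planted_unmutated_precursor_passes_all_flags(self, rng):
        q = make_query(rng)
        bg = random_genome(rng, 2000).sequence
        genome = [GenomeRecord("chr1", bg[:900] + q.sequence + bg[900:])]
        hits = search_homologs(q, genome)
        v = evaluate_candidate(hits[0], q, {r.chrom_id: r.sequence for r in genome})
        assert (v.c1, v.c2, v.c3, v.c4, v.c5, v.c6) == (True,) * 6
        assert v.accepted
        assert v.mfe <= -15

    def test_engineered_oversize_bulge_fails_c5(self, rng):
        # stem - 13-nt one-sided bulge - stem - loop, as a direct fold check
        from oryzamir.hairpin import fold_hairpin, max_bulge

        stem1 = "GCGCGCGCGC"
        stem2 = "ATTATTATTATTATT"  # A/T stem: the C-only bulge cannot pair into it
        bulge = "C" * 13
        seq = stem1 + bulge + stem2 + "AACAA" + revcomp(stem2) + revcomp(stem1)
        s = fold_hairpin(seq)
        assert max_bulge(s) == 13
        th = FilterThresholds()
        assert not (max_bulge(s) <= th.max_bulge)

    def test_gc_matched_shuffles_rarely_accepted(self, rng):
        q = make_query(rng)
        bg = random_genome(rng, 1200).sequence
        genome_dict = {"chr1": bg}
        hit = Hit(
            query_id="q1", chrom="chr1", strand="+", start=100,
            end=100 + len(q.sequence), raw_score=50, bit_score=50, e_value=1e-10,
            aligned_query=q.sequence, aligned_subject=q.sequence, identity=1.0,
        )
        accepted = 0
        n_shuffles = 300
        letters = list(q.sequence)
        for _ in range(n_shuffles):
            rng.shuffle(letters)  # GC-content preserved exactly
            shuffled = "".join(letters)
            gd = {"chr1": bg[:100] + shuffled + bg[100 + len(shuffled):]}
            v = evaluate_candidate(hit, q, gd)
            accepted += v.accepted
        assert accepted / n_shuffles < 0.01


class TestParalogues:
    def _verdict(self, chrom, start, end, qid="q1"):
        hit = Hit(
            query_id=qid, chrom=chrom, strand="+", start=start, end=end,
            raw_score=50, bit_score=50, e_value=1e-12, aligned_query="",
            aligned_subject="", identity=1.0,
        )
        from oryzamir.homology import CandidateVerdict

        return CandidateVerdict(hit=hit, family="f1", c1=True, c2=True, c3=True,
                                c4=True, c5=True, c6=True)

    def test_single_locus_single_group(self):
        vs = group_paralogues([self._verdict("chr1", 0, 100)])
        assert vs[0].paralogue_group == "q1.p0"

    def test_hits_on_different_chromosomes_are_distinct_paralogues(self):
        vs = group_paralogues(
            [self._verdict("chr1", 0, 100), self._verdict("chr7", 500, 600)]
        )
        assert {v.paralogue_group for v in vs} == {"q1.p0", "q1.p1"}

    def test_nearby_hits_share_a_locus(self):
        vs = group_paralogues(
            [self._verdict("chr1", 0, 100), self._verdict("chr1", 150, 250)],
            min_locus_gap=200,
        )
        assert len({v.paralogue_group for v in vs}) == 1


class TestContext:
    FEATS = [
        FeatureRecord("c", 1000, 2000, "+", "gene", "g1"),
        FeatureRecord("c", 1000, 1400, "+", "exon", "g1.e1"),
        FeatureRecord("c", 1600, 2000, "+", "exon", "g1.e2"),
    ]

    @pytest.mark.parametrize(
        "span,expected",
        [
            ((100, 200), "intergenic"),
            ((1450, 1550), "intronic"),
            ((1100, 1200), "exonic"),
            ((1399, 1450), "intron_exon"),  # spans the exon end by 1 nt
        ],
    )
    def test_classification(self, span, expected):
        assert classify_context(("c", *span), self.FEATS) == expected


class TestTEOverlap:
    def test_planted_60nt_fragment_detected(self, rng):
        te = random_genome(rng, 300, "STOWAWAY_1")
        frag = te.sequence[100:160]
        pre = random_genome(rng, 40).sequence + frag + random_genome(rng, 40).sequence
        assert scan_te_overlap(pre, [te]) == ["STOWAWAY"]

    def test_40nt_fragment_below_min_overlap(self, rng):
        te = random_genome(rng, 300, "GYPSY_1")
        frag = te.sequence[100:140]
        pre = random_genome(rng, 50).sequence + frag + random_genome(rng, 50).sequence
        assert scan_te_overlap(pre, [te]) == []

    def test_empty_library_warns_and_returns_nothing(self, rng):
        with pytest.warns(UserWarning, match="empty TE library"):
            assert scan_te_overlap("ACGT" * 30, []) == []
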