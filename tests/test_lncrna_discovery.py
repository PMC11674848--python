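import itertools
import math

import numpy as np
import pytest

from adtrx.io_formats import AnnotationCatalog, GenomicInterval, TranscriptModel
from adtrx.lncrna_discovery import (
    CodingPotentialVote,
    ScorerSet,
    assign_class_code,
    categorize_lncrna,
    consensus_vote,
    fickett_score,
    filter_candidates,
    find_longest_orf,
    gc_content_score,
    hexamer_score,
    orf_coverage_score,
    region_read_distribution,
    train_hexamer_tables,
)
from oracles import class_code_oracle, fickett_oracle, longest_orf_oracle


def _tx(tid, exons, gene=None, strand="+", cds=None, seq="c"):
    return TranscriptModel(
        tid,
        gene or tid,
        tuple(GenomicInterval(seq, s, e, strand) for s, e in exons),
        cds=tuple(GenomicInterval(seq, s, e, strand) for s, e in cds) if cds else None,
    )


class TestCandidateFilter:
    @pytest.mark.parametrize(
        "exons,expect",
        [
            ([(0, 100), (200, 249), (300, 350)], False),  # 199 nt, 3 exons
            ([(0, 100), (200, 300)], True),  # exactly 200 nt, exactly 2 exons
            ([(0, 5000)], False),  # long but single exon
        ],
    )
    def test_length_and_exon_boundaries_inclusive(self, exons, expect):
        cat = AnnotationCatalog([_tx("t", exons)])
        assert (["t"] == filter_candidates(cat)) is expect


class TestLongestOrf:
    def test_minimal_orf(self):
        assert find_longest_orf("ATGAAATGA") == (0, 9, 0)

    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCC") is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 400))))
            got = find_longest_orf(seq)
            want = longest_orf_oracle(seq)
            if want is None:
                assert got is None
            else:
                assert (got[0], got[1]) == want

    def test_tie_broken_to_five_prime(self):
        # two length-9 ORFs in the same frame
        seq = "ATGAAATGACCCATGAAATGA"
        assert find_longest_orf(seq)[0] == 0


class TestFickett:
    def test_matches_table_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert fickett_score(seq) == pytest.approx(fickett_oracle(seq))

    def test_deterministic_and_polya(self):
        seq = "A" * 300
        assert fickett_score(seq) == fickett_score(seq)
        assert fickett_score(seq) == pytest.approx(fickett_oracle(seq))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            fickett_score("ATG" * 10)


class TestHexamer:
    def test_identical_tables_give_zero(self):
        table = {"".join(h): 1 / 4096 for h in itertools.product("ACGT", repeat=6)}
        assert hexamer_score("ATGAAAAAAAAATGA", table, table) == 0.0

    def test_uniform_ratio_closed_form(self):
        coding = {"".join(h): 2 / 4096 for h in itertools.product("ACGT", repeat=6)}
        noncoding = {"".join(h): 1 / 4096 for h in itertools.product("ACGT", repeat=6)}
        seq = "ATG" + "AAACCC" * 4 + "TGA"  # ORF of 30 nt: k in-frame hexamers
        orf = find_longest_orf(seq)
        k = (orf[1] - orf[0] - 5 + 2) // 3  # positions 0,3,.. <= len-6
        assert hexamer_score(seq, coding, noncoding) == pytest.approx(k * math.log(2))

    def test_no_orf_sentinel(self):
        table = {"".join(h): 1 / 4096 for h in itertools.product("ACGT", repeat=6)}
        assert hexamer_score("CCCCCCCCCC", table, table) == -math.inf

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(17)
        cods = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(20)]
        ncs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(20)]
        ct, nt = train_hexamer_tables(cods, ncs)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        orf = find_longest_orf(seq)
        if orf is None:
            return
        expected = 0.0
        orf_seq = seq[orf[0]:orf[1]]
        for p in range(0, len(orf_seq) - 5, 3):
            h = orf_seq[p:p + 6]
            expected += math.log(ct[h] / nt[h])
        assert hexamer_score(seq, ct, nt) == pytest.approx(expected)


class TestSimpleScores:
    @pytest.mark.parametrize(
        "tl,ol,expect", [(600, 0, 0.0), (600, 600, 1.0), (600, 300, 0.5)]
    )
    def test_orf_coverage(self, tl, ol, expect):
        assert orf_coverage_score(tl, ol) == expect

    def test_orf_coverage_invalid(self):
        with pytest.raises(ValueError):
            orf_coverage_score(100, 200)

    def test_gc_content(self):
        assert gc_content_score("GGCC") == 1.0
        assert gc_content_score("ATGC") == 0.5


class TestConsensus:
    def test_exhaustive_32_vectors(self):
        """Of all 2^5 verdict vectors exactly the all-noncoding one is a lncRNA."""
        n_lnc = 0
        for verdicts in itertools.product(["coding", "noncoding"], repeat=5):
            votes = [
                CodingPotentialVote("t", f"s{i}", 0.0, v)
                for i, v in enumerate(verdicts)
            ]
            if consensus_vote(votes) == "lncRNA":
                n_lnc += 1
                assert all(v == "noncoding" for v in verdicts)
        assert n_lnc == 1

    def test_wrong_vote_count(self):
        votes = [CodingPotentialVote("t", "s", 0.0, "noncoding")] * 4
        with pytest.raises(ValueError):
            consensus_vote(votes)

    def test_monotone_in_verdicts(self):
        """Flipping any noncoding verdict to coding never creates a lncRNA."""
        base = [
            CodingPotentialVote("t", f"s{i}", 0.0, "noncoding") for i in range(5)
        ]
        for i in range(5):
            flipped = list(base)
            flipped[i] = CodingPotentialVote("t", f"s{i}", 0.0, "coding")
            assert consensus_vote(flipped) == "not-lncRNA"


class TestClassCodes:
    @pytest.fixture()
    def ref(self):
        # one gene with exons [1000,2000) [4000,6000)... wait intron [2000,4000)
        return AnnotationCatalog(
            [
                _tx("R1", [(1000, 2000), (4000, 6000), (7000, 7500)], gene="RG1"),
                _tx("R2", [(20000, 20500), (21000, 21400)], gene="RG2"),
            ]
        )

    def test_intronic(self, ref):
        q = _tx("q", [(2100, 2400), (2600, 2900)])
        assert assign_class_code(q, ref).code == "i"

    def test_intergenic(self, ref):
        q = _tx("q", [(10000, 10300), (10500, 10800)])
        code = assign_class_code(q, ref)
        assert code.code == "u" and code.evidence == ()

    def test_exonic_overlap(self, ref):
        q = _tx("q", [(1100, 1300), (4100, 4300)])
        assert assign_class_code(q, ref).code == "x"

    def test_partial_overlap(self, ref):
        q = _tx("q", [(1500, 2500), (4100, 4200)])
        assert assign_class_code(q, ref).code == "o"

    def test_matches_per_base_oracle_on_random_catalogs(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            ref = AnnotationCatalog()
            pos = 0
            for g in range(int(rng.integers(1, 4))):
                exons = []
                pos += int(rng.integers(100, 500))
                for _ in range(int(rng.integers(1, 4))):
                    ln = int(rng.integers(80, 300))
                    exons.append((pos, pos + ln))
                    pos += ln + int(rng.integers(100, 400))
                ref.add(_tx(f"R{g}", exons, gene=f"RG{g}"))
            for q in range(10):
                s = int(rng.integers(0, max(1, pos)))
                exons = []
                p = s
                for _ in range(int(rng.integers(1, 3))):
                    ln = int(rng.integers(40, 250))
                    exons.append((p, p + ln))
                    p += ln + int(rng.integers(40, 200))
                t = _tx(f"q{q}", exons)
                assert assign_class_code(t, ref).code == class_code_oracle(t, ref)


class TestCategories:
    def test_precedence_antisense_over_intronic(self):
        ref = AnnotationCatalog([_tx("R1", [(0, 1000), (3000, 4000)], gene="RG")])
        q = _tx("q", [(1200, 1400), (1600, 1800)], strand="-")
        code = assign_class_code(q, ref)
        assert code.code == "i"
        assert categorize_lncrna(q, code, ref) == "antisense"

    def test_intergenic_and_intronic(self):
        ref = AnnotationCatalog([_tx("R1", [(0, 1000), (3000, 4000)], gene="RG")])
        far = _tx("far", [(10000, 10200), (10400, 10600)])
        code = assign_class_code(far, ref)
        assert categorize_lncrna(far, code, ref) == "intergenic"
        inside = _tx("in", [(1200, 1400), (1600, 1800)])
        assert categorize_lncrna(inside, assign_class_code(inside, ref), ref) == "intronic"

    def test_unmatched_defaults_with_warning(self):
        ref = AnnotationCatalog([_tx("R1", [(0, 1000)], gene="RG")])
        q = _tx("q", [(500, 1500)])  # same-strand partial overlap
        code = assign_class_code(q, ref)
        with pytest.warns(UserWarning):
            assert categorize_lncrna(q, code, ref) == "intergenic"


class TestRegionDistribution:
    @pytest.fixture()
    def ref(self):
        # + strand gene: exon1 [20000,21000) CDS [20200,20800), intron
        # [21000,22000), exon2 [22000,23000) all 3'UTR beyond CDS end
        return AnnotationCatalog(
            [
                _tx(
                    "R1",
                    [(20000, 21000), (22000, 23000)],
                    gene="RG",
                    cds=[(20200, 20800)],
                )
            ]
        )

    def test_precedence_and_examples(self, ref):
        reads = [
            GenomicInterval("c", 20300, 20400),  # inside CDS
            GenomicInterval("c", 20700, 21200),  # spans CDS and intron -> CDS
            GenomicInterval("c", 21100, 21200),  # intron
            GenomicInterval("c", 22100, 22200),  # 3'UTR exon
            GenomicInterval("c", 10001, 10100),  # 9999 bp upstream of TSS
            GenomicInterval("c", 1, 100),  # beyond 10 kb -> unassigned
        ]
        frac = region_read_distribution(reads, ref)
        assert frac["CDS"] == pytest.approx(2 / 5)
        assert frac["intron"] == pytest.approx(1 / 5)
        assert frac["three_prime_utr"] == pytest.approx(1 / 5)
        assert frac["upstream"] == pytest.approx(1 / 5)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_order_invariance(self, ref):
        rng = np.random.default_rng(2)
        reads = [
            GenomicInterval("c", int(s), int(s) + 50)
            for s in rng.integers(9000, 24000, size=40)
        ]
        a = region_read_distribution(reads, ref)
        b = region_read_distribution(list(reversed(reads)), ref)
        assert a == b


class TestCalibratedPipeline:
    def test_scores_complete_and_thresholded(self, scorers):
        seq = "ATGAAA" * 60 + "TGA"
        scores = scorers.scores(seq)
        assert set(scores) == {"fickett", "hexamer", "orf_coverage", "orf_length", "gc_content"}
        votes = scorers.votes("t", seq)
        assert len(votes) == 5

    def test_missing_threshold_rejected(self):
        table = {"A" * 6: 1.0}
        with pytest.raises(ValueError, match="thresholds"):
            ScorerSet(table, table, {"fickett": 0.5})
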