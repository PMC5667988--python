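"""Orientation, intergenic arithmetic, CpG/TATA/PWM sequence features."""

import itertools
import re

import numpy as np
import pytest

from adjacoex.model import GeneAnnotation, GeneRecord, GenomicInterval, ValidationError
from adjacoex.promoters import (
    CONVERGENT,
    DIVERGENT,
    TANDEM,
    MotifHit,
    Pwm,
    classify_orientation,
    cpg_island_scan,
    find_bidirectional_pairs,
    intergenic_interval,
    pwm_scan,
    read_jaspar_pwms,
    reverse_complement,
    tata_scan,
)


def _gene(gid, start, end, strand, chrom="chr20"):
    return GeneRecord(gid, gid, GenomicInterval(chrom, start, end, strand))


class TestOrientation:
    @pytest.mark.parametrize(
        "left_strand,right_strand,expected",
        [
            ("-", "+", DIVERGENT),
            ("+", "-", CONVERGENT),
            ("+", "+", TANDEM),
            ("-", "-", TANDEM),
        ],
    )
    def test_all_strand_combinations(self, left_strand, right_strand, expected):
        a = _gene("a", 100, 200, left_strand)
        b = _gene("b", 500, 700, right_strand)
        assert classify_orientation(a, b) == expected
        # insensitive to argument order
        assert classify_orientation(b, a) == expected

    def test_unstranded_gene_is_an_error(self):
        with pytest.raises(ValidationError, match="unstranded"):
            classify_orientation(_gene("a", 0, 10, "."), _gene("b", 20, 30, "+"))

    def test_different_chromosomes_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_orientation(
                _gene("a", 0, 10, "+"), _gene("b", 20, 30, "+", chrom="chr1")
            )


class TestIntergenic:
    def test_printed_promoter_interval_is_89_bp(self):
        left = _gene("PLAGL2", 32192500, 32207791, "-")
        right = _gene("POFUT1", 32207880, 32213357, "+")
        iv, dist, overlap = intergenic_interval(left, right)
        assert (iv.start, iv.end) == (32207791, 32207880)
        assert dist == 89 and iv.length == 89
        assert not overlap

    def test_abutting_genes_distance_zero(self):
        iv, dist, overlap = intergenic_interval(
            _gene("a", 0, 100, "-"), _gene("b", 100, 200, "+")
        )
        assert dist == 0 and iv.length == 0 and not overlap

    def test_overlapping_genes_flagged(self):
        iv, dist, overlap = intergenic_interval(
            _gene("a", 0, 150, "-"), _gene("b", 100, 200, "+")
        )
        assert dist == 0 and overlap


class TestBidirectionalPairs:
    def test_planted_pair_flagged(self, bundle):
        annotation, truth = bundle[0], bundle[2]
        flagged = [
            p for p in find_bidirectional_pairs(annotation) if p.bidirectional_flag
        ]
        assert [(p.gene_left, p.gene_right) for p in flagged] == [
            (t[0], t[1]) for t in truth.divergent_pairs
        ]

    def test_strict_max_dist_boundary(self, bundle):
        annotation = bundle[0]
        flagged = [
            p
            for p in find_bidirectional_pairs(annotation, max_dist=89)
            if p.bidirectional_flag
        ]
        assert flagged == []

    def test_agrees_with_brute_force_over_random_annotations(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pos, recs = 0, []
            for i in range(100):
                pos += int(rng.integers(0, 2000))
                length = int(rng.integers(200, 3000))
                recs.append(
                    _gene(f"g{i}", pos, pos + length, str(rng.choice(["+", "-"])))
                )
                pos += length
            ann = GeneAnnotation(recs)
            got = {
                (p.gene_left, p.gene_right)
                for p in find_bidirectional_pairs(ann, max_dist=1000)
                if p.bidirectional_flag
            }
            # oracle: scan consecutive pairs directly off the sorted records
            expect = set()
            srt = sorted(recs, key=lambda r: r.interval.start)
            for a, b in zip(srt, srt[1:]):
                dist = b.interval.start - a.interval.end
                if (
                    a.interval.strand == "-"
                    and b.interval.strand == "+"
                    and 0 <= dist < 1000
                ):
                    expect.add((a.gene_id, b.gene_id))
            assert got == expect


class TestCpGIslands:
    def test_poly_a_has_no_islands(self):
        assert cpg_island_scan("A" * 400) == []

    def test_cg_repeat_is_one_full_island(self):
        seq = "CG" * 150
        islands = cpg_island_scan(seq)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (0, 300)
        assert isl.gc_fraction == pytest.approx(1.0)
        # obs/exp = (150*300)/(150*150) = 2
        assert isl.obs_exp_cpg == pytest.approx(2.0)

    def test_sequence_shorter_than_window_yields_nothing(self):
        assert cpg_island_scan("CG" * 20, window=100) == []

    def test_generator_spacer_found_with_lowered_length(self, bundle):
        truth = bundle[2]
        seq = next(iter(truth.spacer_seqs.values()))
        islands = cpg_island_scan(seq, len_min=50, window=50)
        assert len(islands) == 1

    def test_islands_disjoint_after_merge(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=2000))
        islands = cpg_island_scan(seq, len_min=100)
        for a, b in zip(islands, islands[1:]):
            assert a.end <= b.start


class TestTata:
    def test_gc_sequence_negative(self):
        assert tata_scan("GCGCGCGC")[0] is False

    def test_consensus_instance_found_at_offset(self):
        found, hits = tata_scan("GGGGTATAAAAGGG")
        assert found and (4, "+") in hits

    def test_agrees_with_substring_oracle_both_strands(self):
        consensus = {
            "TATA" + w1 + "A" + w2 for w1 in "AT" for w2 in "AT"
        }
        rng = np.random.default_rng(7)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            windows = {seq[i : i + 7] for i in range(len(seq) - 6)}
            rc = reverse_complement(seq)
            windows |= {rc[i : i + 7] for i in range(len(rc) - 6)}
            assert tata_scan(seq)[0] == bool(windows & consensus)


def _consensus_pwm(consensus: str, pseudocount: float = 0.0) -> Pwm:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, base_idx[b]] = 1.0
    return Pwm("consensus", mat, pseudocount=pseudocount)


class TestPwm:
    def test_consensus_scores_maximum_at_offset_zero(self):
        pwm = _consensus_pwm("ACGT")
        hits = pwm_scan("ACGT", pwm, threshold_bits=7.9)
        plus = [h for h in hits if h.strand == "+"]
        assert plus == [MotifHit("consensus", 0, "+", pytest.approx(4 * 2.0))]
        assert pwm.max_score == pytest.approx(4 * np.log2(1 / 0.25))

    def test_palindromic_pwm_hits_mirror_across_strands(self):
        pwm = _consensus_pwm("ACGT")  # reverse complement of ACGT is ACGT
        hits = pwm_scan("TTACGTTT", pwm, threshold_bits=7.9)
        offsets = {s: {h.offset for h in hits if h.strand == s} for s in "+-"}
        assert offsets["+"] == offsets["-"] == {2}

    def test_hit_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = Pwm("m", rng.random((6, 4)) + 0.05)
        counts = [len(pwm_scan(seq, pwm, t)) for t in (-5, 0, 2, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_scoring_oracle(self):
        rng = np.random.default_rng(5)
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for _ in range(50):
            width = int(rng.integers(4, 9))
            pwm = Pwm("m", rng.random((width, 4)) + 0.01)
            seq = "".join(rng.choice(list("ACGT"), size=60))
            threshold = float(rng.uniform(-2, pwm.max_score))
            lo = pwm.log_odds()
            expect = set()
            for off in range(len(seq) - width + 1):
                window = seq[off : off + width]
                s_fwd = sum(lo[i, base_idx[b]] for i, b in enumerate(window))
                s_rev = sum(
                    lo[i, base_idx[b]]
                    for i, b in enumerate(reverse_complement(window))
                )
                if s_fwd >= threshold:
                    expect.add((off, "+"))
                if s_rev >= threshold:
                    expect.add((off, "-"))
            got = {(h.offset, h.strand) for h in pwm_scan(seq, pwm, threshold)}
            assert got == expect

    def test_n_bases_disqualify_windows(self):
        pwm = _consensus_pwm("ACGT")
        assert pwm_scan("ACNT", pwm, threshold_bits=-100) == []

    def test_zero_width_matrix_rejected(self):
        with pytest.raises(ValidationError):
            Pwm("empty", np.zeros((0, 4)))

    def test_jaspar_parsing(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0003.1 TFAP2C\n"
            "A [ 0 10  0 ]\n"
            "C [10  0  0 ]\n"
            "G [ 0  0 10 ]\n"
            "T [ 0  0  0 ]\n"
        )
        pwms = read_jaspar_pwms(p)
        assert len(pwms) == 1
        assert pwms[0].width == 3
        hits = pwm_scan("CAG", pwms[0], threshold_bits=5.0)
        assert any(h.offset == 0 and h.strand == "+" for h in hits)
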