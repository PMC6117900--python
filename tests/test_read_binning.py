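"""The read-binning score cascade: S' filter, specificities, vicinity,
read scores and barcode scores."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metabarcode.read_binning import (
    AlignmentPool,
    ReadHit,
    align_reads_to_barcodes,
    apply_sprime_filter,
    bin_reads,
    classify,
    compute_alignment_specificity,
    compute_barcode_scores,
    compute_read_specificity,
    compute_sprime,
    compute_vicinity,
    jaccard_distance_matrix,
    read_score1,
    read_score2,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestReadAlignment:
    def test_exact_substring_scores_full_length(self):
        rng = np.random.default_rng(0)
        barcode = _random_seq(rng, 3000)
        read = barcode[1000:1250]
        hits, n = align_reads_to_barcodes([("r1", read)], {"b1": barcode})
        assert n == 1
        assert len(hits) == 1
        assert hits[0].raw_score == 250.0
        assert hits[0].read_length == 250

    def test_reverse_complement_read_found(self):
        rng = np.random.default_rng(1)
        barcode = _random_seq(rng, 3000)
        read = barcode[500:750]
        rc = read.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hits, _ = align_reads_to_barcodes([("r1", rc)], {"b1": barcode})
        assert hits and hits[0].raw_score == 250.0

    def test_shuffled_reads_rarely_hit(self):
        """Reads with the barcode's composition but shuffled order are an
        empirical null: at most 2 of 100 may produce a reportable hit."""
        rng = np.random.default_rng(2)
        barcode = _random_seq(rng, 5000)
        reads = []
        for i in range(100):
            chars = list(barcode[i * 40 : i * 40 + 250])
            rng.shuffle(chars)
            reads.append((f"r{i}", "".join(chars)))
        hits, _ = align_reads_to_barcodes(reads, {"b1": barcode})
        assert len(hits) <= 2

    def test_shared_gene_hits_both_barcodes_equally(self):
        rng = np.random.default_rng(3)
        shared = _random_seq(rng, 900)
        b1 = _random_seq(rng, 1000) + shared + _random_seq(rng, 1000)
        b2 = _random_seq(rng, 500) + shared + _random_seq(rng, 1500)
        read = shared[300:550]
        hits, _ = align_reads_to_barcodes([("r1", read)], {"b1": b1, "b2": b2})
        assert sorted(h.barcode_id for h in hits) == ["b1", "b2"]
        assert hits[0].raw_score == hits[1].raw_score == 250.0

    def test_empty_barcode_set_rejected(self):
        with pytest.raises(ValueError):
            align_reads_to_barcodes([("r1", "ACGT")], {})

    def test_gapless_fast_path_matches_full_dp(self):
        """Scores from the diagonal fast path equal the affine-gap dynamic
        programming on reads with substitutions only."""
        from metabarcode import _align

        rng = np.random.default_rng(4)
        barcode = _random_seq(rng, 4000)
        aligner = _align.nucleotide_aligner("local")
        for start in (100, 900, 2400):
            read = list(barcode[start : start + 275])
            for pos in rng.integers(0, 275, size=20):  # ~7% divergence
                read[pos] = "ACGT"[(("ACGT".index(read[pos]) + 1) % 4)]
            read = "".join(read)
            hits, _ = align_reads_to_barcodes([("r", read)], {"b": barcode})
            assert hits
            assert hits[0].raw_score == aligner.score(barcode, read)


class TestSPrime:
    def test_worked_value(self):
        """Term-by-term evaluation of the filter formula at
        S=100, L=250, N=1000."""
        S, L, N = 100.0, 250.0, 1000
        middle = (L - S) / (1 + math.exp(3 * (L - S) / (S * math.log10(N))))
        last = 10 * (math.log((2 * S + 100) / (L + 100)) - 1)
        expected = S + middle - last
        assert compute_sprime(S, L, N) == pytest.approx(expected, rel=1e-9)
        assert compute_sprime(S, L, N) == pytest.approx(138.905, abs=1e-3)

    def test_collapse_when_mean_score_equals_length(self):
        S = L = 200.0
        expected = S - 10 * (math.log((2 * S + 100) / (L + 100)) - 1)
        assert compute_sprime(S, L, 100) == pytest.approx(expected, rel=1e-12)

    def test_exceeds_mean_when_reads_longer_than_scores(self):
        sprime = compute_sprime(200.0, 250.0, 10)
        assert sprime > 200.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_sprime(0.0, 250.0, 100)
        with pytest.raises(ValueError):
            compute_sprime(100.0, 250.0, 1)

    def test_filter_drops_weak_hits_keeps_prefilter_stats(self):
        hits = [
            ReadHit("r1", "b1", 250.0, 250),
            ReadHit("r2", "b1", 50.0, 250),
            ReadHit("r3", "b2", 240.0, 250),
        ]
        pool = AlignmentPool.from_hits(hits, n_barcodes=2, n_reads_total=10)
        filtered = apply_sprime_filter(pool)
        assert filtered.S == pool.S  # pre-filter statistics preserved
        assert filtered.N == 3
        kept = {h.read_id for h in filtered.hits}
        assert "r2" not in kept

    def test_filter_skipped_for_single_read(self):
        hits = [ReadHit("r1", "b1", 100.0, 250)]
        pool = AlignmentPool.from_hits(hits, n_barcodes=2, n_reads_total=10)
        filtered = apply_sprime_filter(pool)
        assert filtered.hits == hits
        assert filtered.sprime is None


class TestSpecificities:
    @pytest.mark.parametrize(
        "aligned,matches,barcodes,expected",
        [
            (100, 100, 5, 1.0),  # every read matches one barcode
            (100, 500, 5, 0.0),  # every read matches every barcode
            (10, 16, 4, 0.8),
        ],
    )
    def test_alignment_specificity(self, aligned, matches, barcodes, expected):
        assert compute_alignment_specificity(aligned, matches, barcodes) == pytest.approx(
            expected
        )

    def test_alignment_specificity_single_barcode(self):
        assert compute_alignment_specificity(10, 10, 1) == 1.0

    @pytest.mark.parametrize(
        "hit,total,expected",
        [(1, 9, 1.0), (9, 9, 0.0), (3, 9, 0.75)],
    )
    def test_read_specificity(self, hit, total, expected):
        assert compute_read_specificity(hit, total) == pytest.approx(expected)

    def test_read_specificity_domain(self):
        with pytest.raises(ValueError):
            compute_read_specificity(0, 9)
        with pytest.raises(ValueError):
            compute_read_specificity(10, 9)


VICINITY_SETS = {
    "A": {"r1", "r2", "r3"},
    "B": {"r1", "r2", "r4"},
    "C": {"r5", "r6"},
}


class TestVicinity:
    def test_hand_computed_matrix(self):
        matrix = jaccard_distance_matrix(VICINITY_SETS)
        assert matrix[("A", "B")] == pytest.approx(0.5)
        assert matrix[("A", "C")] == 1.0
        assert matrix[("B", "C")] == 1.0
        # symmetric
        assert matrix[("B", "A")] == matrix[("A", "B")]

    def test_shared_read_scaled_by_matrix_maximum(self):
        vic = compute_vicinity(VICINITY_SETS)
        assert vic["r1"] == pytest.approx(5.0)  # 10 * 0.5 / 1.0
        assert vic["r2"] == pytest.approx(5.0)

    def test_single_barcode_read_is_zero(self):
        vic = compute_vicinity(VICINITY_SETS)
        assert vic["r5"] == 0.0
        assert vic["r3"] == 0.0

    def test_identical_read_sets_degenerate_to_zero(self):
        sets = {"A": {"r1", "r2"}, "B": {"r1", "r2"}, "C": {"r1", "r2"}}
        vic = compute_vicinity(sets)
        assert all(v == 0.0 for v in vic.values())

    @given(st.integers(0, 10_000))
    def test_bounds_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_barcodes = int(rng.integers(2, 11))
        n_reads = int(rng.integers(1, 30))
        sets = {f"b{j}": set() for j in range(n_barcodes)}
        for i in range(n_reads):
            k = int(rng.integers(1, n_barcodes + 1))
            for j in rng.choice(n_barcodes, size=k, replace=False):
                sets[f"b{j}"].add(f"r{i}")
        vic = compute_vicinity(sets)
        hit_counts = {r: sum(r in s for s in sets.values()) for r in vic}
        for read_id, v in vic.items():
            assert 0.0 <= v <= 10.0
            if hit_counts[read_id] == 1:
                assert v == 0.0


class TestReadScores:
    def test_specific_read_factor_collapses_to_one(self):
        # r_spec = 1, r_vic = 0 -> correction factor (1+1+1)/(1+1+1) = 1
        assert read_score1(0.9, 1.0, 0.0) == pytest.approx(0.9)

    def test_read_score2_collapse(self):
        # additionally a = 1: only the abundance ratio remains
        assert read_score2(0.9, 1.0, 0.0, 1.0, 30, 100) == pytest.approx(0.9 * 0.3)

    def test_read_score1_direct_evaluation(self):
        expected = 0.9 * (0.5 + math.exp(2.5) + 1) / (0.5 + math.exp(5.0) + 1)
        got = read_score1(0.9, 0.5, 5.0)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(0.0821, abs=2e-4)

    def test_read_score2_direct_evaluation(self):
        expected = (
            0.8
            * (40 / 200)
            * 0.9
            * (0.5 + 1.5 ** 2.5 + 1)
            / (0.5 + 1.5 ** 5.0 + 1)
        )
        assert read_score2(0.9, 0.5, 5.0, 0.8, 40, 200) == pytest.approx(
            expected, rel=1e-9
        )

    @given(
        r_spec=st.floats(0, 1),
        r_vic=st.floats(0, 10),
    )
    def test_promiscuity_factor_at_most_one(self, r_spec, r_vic):
        factor = read_score1(1.0, r_spec, r_vic)
        assert factor <= 1.0 + 1e-12
        if r_vic == 0.0 or r_spec == 1.0:
            assert factor == pytest.approx(1.0)


def _uniform_pool(hits, n_barcodes, n_reads_total=100):
    return AlignmentPool.from_hits(hits, n_barcodes, n_reads_total)


class TestBarcodeScores:
    def test_empty_pool_scores_zero_all_absent(self):
        pool = _uniform_pool([], 3)
        result = compute_barcode_scores(pool, {"b1": 1000, "b2": 1000, "b3": 1000})
        for call in result.calls.values():
            assert call.score1 == 0.0
            assert call.score2 == 0.0
            assert not call.present

    def test_unhit_barcode_scores_zero_and_absent(self):
        hits = [ReadHit(f"r{i}", "b1", 250.0, 250) for i in range(20)]
        pool = _uniform_pool(hits, 2)
        result = compute_barcode_scores(pool, {"b1": 1000, "b2": 1000})
        assert result.calls["b2"].score1 == 0.0
        assert not result.calls["b2"].present
        assert result.calls["b1"].score1 > 0.0

    def test_micro_case_matches_term_by_term_oracle(self):
        """Three barcodes, six reads: the pipeline's barcode scores equal an
        independent spreadsheet-style evaluation of the whole cascade."""
        lengths = {"A": 2000, "B": 2000, "C": 4000}
        table = [
            # read_id, barcode, raw, read_len
            ("r1", "A", 240.0, 250),
            ("r1", "B", 200.0, 250),
            ("r2", "A", 250.0, 250),
            ("r3", "B", 300.0, 300),
            ("r4", "C", 220.0, 275),
            ("r5", "C", 180.0, 200),
            ("r6", "A", 260.0, 260),
            ("r6", "C", 150.0, 260),
        ]
        hits = [ReadHit(r, b, s, l) for r, b, s, l in table]
        pool = _uniform_pool(hits, 3, n_reads_total=6)
        result = compute_barcode_scores(pool, lengths)

        # ---- independent evaluation, plain arithmetic ----
        reads_of = {
            "A": {"r1", "r2", "r6"},
            "B": {"r1", "r3"},
            "C": {"r4", "r5", "r6"},
        }
        n_aligned = 6
        n_matches = 8
        a = 1 - (n_matches - n_aligned) / (n_aligned * 2)

        def jac(x, y):
            return 1 - len(reads_of[x] & reads_of[y]) / len(reads_of[x] | reads_of[y])

        dmax = max(jac("A", "B"), jac("A", "C"), jac("B", "C"))
        r_vic = {
            "r1": 10 * jac("A", "B") / dmax,
            "r6": 10 * jac("A", "C") / dmax,
        }
        r_spec = {r: (3 - 1) / 2 for r in ("r2", "r3", "r4", "r5")}
        r_spec.update({"r1": (3 - 2) / 2, "r6": (3 - 2) / 2})

        def rs1(raw, length, r):
            v = r_vic.get(r, 0.0)
            s = r_spec[r]
            return (raw / length) * (s + math.exp(s * v) + 1) / (s + math.exp(v) + 1)

        def rs2(raw, length, r, barcode):
            v = r_vic.get(r, 0.0)
            s = r_spec[r]
            return (
                a
                * (len(reads_of[barcode]) / n_aligned)
                * (raw / length)
                * (s + 1.5 ** (s * v) + 1)
                / (s + 1.5 ** v + 1)
            )

        total_len = sum(lengths.values())
        for barcode in lengths:
            bhits = [(r, b, s, l) for r, b, s, l in table if b == barcode]
            t_i = sum(s / l for _, _, s, l in bhits)
            sum1 = sum(rs1(s, l, r) for r, _, s, l in bhits)
            sum2 = sum(rs2(s, l, r, barcode) for r, _, s, l in bhits)
            denom = 1 + 3 * lengths[barcode] * t_i / (4 * total_len)
            assert result.calls[barcode].score1 == pytest.approx(
                (1 + sum1) / denom - 1, rel=1e-9
            )
            assert result.calls[barcode].score2 == pytest.approx(
                (1 + sum2) / denom - 1, rel=1e-9
            )

    def test_scores_invariant_under_uniform_length_rescaling(self):
        hits = [
            ReadHit("r1", "b1", 250.0, 250),
            ReadHit("r2", "b1", 240.0, 250),
            ReadHit("r3", "b2", 250.0, 250),
        ]
        lengths = {"b1": 1000, "b2": 3000}
        doubled = {b: 2 * v for b, v in lengths.items()}
        r1 = compute_barcode_scores(_uniform_pool(hits, 2), lengths)
        r2 = compute_barcode_scores(_uniform_pool(hits, 2), doubled)
        for b in lengths:
            assert r1.calls[b].score1 == pytest.approx(r2.calls[b].score1, rel=1e-12)
            assert r1.calls[b].score2 == pytest.approx(r2.calls[b].score2, rel=1e-12)

    def test_score1_non_decreasing_in_specific_reads(self):
        lengths = {"b1": 1000, "b2": 1000}
        previous = -1.0
        for n in (1, 3, 10, 30, 100):
            hits = [ReadHit(f"r{i}", "b1", 250.0, 250) for i in range(n)]
            result = compute_barcode_scores(_uniform_pool(hits, 2), lengths)
            assert result.calls["b1"].score1 >= previous
            previous = result.calls["b1"].score1

    def test_read_score1_identical_across_barcodes(self):
        """A read hitting two barcodes contributes the same ReadScore1 to
        both (ReadScore2 may differ)."""
        hits = [
            ReadHit("r1", "b1", 250.0, 250),
            ReadHit("r1", "b2", 250.0, 250),
            ReadHit("r2", "b1", 250.0, 250),
        ]
        pool = _uniform_pool(hits, 3)
        result = compute_barcode_scores(pool, {"b1": 1000, "b2": 1000, "b3": 1000})
        assessment = result.assessments["r1"]
        s1_b1 = read_score1(1.0, assessment.r_specificity, assessment.r_vicinity)
        s1_b2 = read_score1(1.0, assessment.r_specificity, assessment.r_vicinity)
        assert s1_b1 == s1_b2


class TestClassification:
    def test_boundary_counts_as_present(self):
        hits = [ReadHit("r1", "b1", 250.0, 250)]
        result = compute_barcode_scores(_uniform_pool(hits, 2), {"b1": 1000, "b2": 1000})
        result.calls["b1"].score1 = 2.3
        result.calls["b1"].score2 = 0.5
        classify(result)
        assert result.calls["b1"].present

    def test_and_rule(self):
        hits = [ReadHit("r1", "b1", 250.0, 250)]
        result = compute_barcode_scores(_uniform_pool(hits, 2), {"b1": 1000, "b2": 1000})
        result.calls["b1"].score1 = 5.0
        result.calls["b1"].score2 = 0.1
        classify(result)
        assert not result.calls["b1"].present


class TestEndToEnd:
    def test_abundant_genome_called_present(self):
        # NB the default cut-off 2.3 is only reachable with >= 3 barcodes:
        # BarcodeScore1 saturates at 4/3 * n_barcodes * read_share - 1
        rng = np.random.default_rng(9)
        b1 = _random_seq(rng, 4000)
        decoys = {f"b{j}": _random_seq(rng, 4000) for j in (2, 3)}
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 3750))
            reads.append((f"r{i}", b1[start : start + 250]))
        result = bin_reads(reads, {"b1": b1, **decoys})
        assert result.calls["b1"].present
        assert not result.calls["b2"].present
        assert not result.calls["b3"].present
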