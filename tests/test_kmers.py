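"""k-mer counting, background correction, dedup and chi-squared enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipmotif.kmers import (
    ClipTag,
    KmerTable,
    all_kmers,
    chi_squared_enrichment,
    classify_core_motif,
    correct_background,
    count_kmers,
    deduplicate_tags,
    kmer_index,
    kmer_string,
    rank_recovery_curve,
    tag_fraction_all,
    tag_fraction_containing,
)

from conftest import make_tag, random_seq


def brute_force_counts(sequences, k):
    """Independent oracle: dictionary sliding-window count, skipping N windows."""
    counts = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    return counts


class TestCountKmers:
    def test_single_window(self):
        t = count_kmers(["AGAAGA"], 6)
        assert t.as_dict() == {"AGAAGA": 1}
        assert t.total_windows == 1

    def test_sliding_window(self):
        t = count_kmers(["AGAAGAA"], 6)
        assert t.as_dict() == {"AGAAGA": 1, "GAAGAA": 1}

    def test_n_windows_skipped(self):
        t = count_kmers(["AGNAGA"], 3)
        assert t.as_dict() == {"AGA": 1}  # only the last window is N-free

    def test_short_sequences_contribute_nothing(self):
        assert count_kmers(["ACG"], 6).total_windows == 0

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["ACGU"], 2)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["ACGT"], 0)

    def test_matches_brute_force_on_random_sequence(self, rng):
        seqs = [random_seq(rng, 1000), random_seq(rng, 257), "AG" + "N" * 5 + random_seq(rng, 50)]
        for k in (1, 3, 6):
            table = count_kmers(seqs, k)
            assert table.as_dict() == brute_force_counts(seqs, k)

    def test_frequencies_sum_to_one(self, rng):
        table = count_kmers([random_seq(rng, 5000)], 6)
        assert table.frequencies().sum() == pytest.approx(1.0, abs=1e-12)

    def test_kmer_string_index_roundtrip(self):
        for km in ("AAAAAA", "TTTTTT", "AGAAGA", "CGTACG"):
            assert kmer_string(kmer_index(km), 6) == km


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        a = make_tag("ACGTACGT", start=0, tag_id="a")
        b = make_tag("ACGTACGT", start=0, tag_id="b")
        assert len(deduplicate_tags([a, b])) == 1

    def test_opposite_strands_never_collide(self):
        a = make_tag("ACGTACGT", start=0, strand="+", tag_id="a")
        b = make_tag("ACGTACGT", start=0, strand="-", tag_id="b")
        assert len(deduplicate_tags([a, b])) == 2

    def test_greedy_chain(self):
        # A[0,40) B[20,60) C[50,90): greedy left-to-right keeps A and C
        a = make_tag("A" * 40, start=0, tag_id="A")
        b = make_tag("C" * 40, start=20, tag_id="B")
        c = make_tag("G" * 40, start=50, tag_id="C")
        kept = deduplicate_tags([b, c, a])  # order-independent input
        assert sorted(t.tag_id for t in kept) == ["A", "C"]

    def test_idempotent(self, small_dataset):
        once = deduplicate_tags(small_dataset.tags)
        assert deduplicate_tags(once) == once

    def test_kept_tags_never_overlap_on_a_strand(self, small_dataset):
        kept = deduplicate_tags(small_dataset.tags)
        by_group = {}
        for t in kept:
            by_group.setdefault((t.chrom, t.strand), []).append(t)
        for group in by_group.values():
            group.sort(key=lambda t: t.start)
            for prev, nxt in zip(group, group[1:]):
                assert nxt.start >= prev.end


class TestBackgroundCorrection:
    @staticmethod
    def _table(counts_dict, k=2):
        counts = np.zeros(4**k, dtype=np.int64)
        for km, c in counts_dict.items():
            counts[kmer_index(km)] = c
        return KmerTable(k=k, counts=counts)

    def test_subtraction_is_exact(self):
        clip = self._table({"AA": 20, "CC": 80})
        genome = self._table({"AA": 5, "CC": 95})
        tx = self._table({"AA": 10, "CC": 90})
        df = correct_background(clip, genome, tx).set_index("kmer")
        assert df.loc["AA", "corrected_genome"] == pytest.approx(0.20 - 0.05)
        assert df.loc["AA", "corrected_transcriptome"] == pytest.approx(0.20 - 0.10)

    def test_identical_tables_give_zero_correction(self):
        t = self._table({"AC": 3, "GT": 7})
        df = correct_background(t, t, t)
        assert np.allclose(df["corrected_genome"], 0.0)

    def test_ranks_are_a_permutation_with_lexicographic_ties(self):
        t = self._table({"AA": 1, "AC": 1, "TT": 2})
        df = correct_background(t, t, t)  # all corrected values tie at 0
        assert sorted(df["rank_corrected"]) == list(range(1, 17))
        # ties broken lexicographically: AA before AC before ... before TT
        assert list(df.sort_values("rank_corrected")["kmer"]) == all_kmers(2)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            correct_background(self._table({"AA": 1}), self._table({"AA": 1}),
                               KmerTable(k=3, counts=np.ones(64, dtype=np.int64)))

    def test_empty_table_rejected(self):
        empty = KmerTable(k=2, counts=np.zeros(16, dtype=np.int64))
        full = self._table({"AA": 1})
        with pytest.raises(ValueError):
            correct_background(full, empty, full)


@pytest.mark.parametrize(
    "kmer,expected",
    [("AGAAGA", "GAA"), ("AGACCC", "AGA"), ("CCCCCC", "other"),
     ("GAAAGA", "GAA"), ("TTTAGA", "AGA")],
)
def test_classify_core_motif(kmer, expected):
    assert classify_core_motif(kmer) == expected


class TestChiSquared:
    def test_equal_proportions_give_zero(self):
        res = chi_squared_enrichment(10, 100, 100, 1000)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        # table [[10,90],[5,95]]: sum (O-E)^2/E by hand
        a, b, c, d = 10.0, 90.0, 5.0, 95.0
        n = a + b + c + d
        expected = [(a + b) * (a + c) / n, (a + b) * (b + d) / n,
                    (c + d) * (a + c) / n, (c + d) * (b + d) / n]
        stat_hand = sum((o - e) ** 2 / e for o, e in zip([a, b, c, d], expected))
        res = chi_squared_enrichment(10, 100, 5, 100)
        assert res.statistic == pytest.approx(stat_hand, rel=1e-12)

    def test_agrees_with_scipy(self):
        from scipy.stats import chi2_contingency

        res = chi_squared_enrichment(17, 300, 52, 2100)
        stat, p, _, _ = chi2_contingency([[17, 283], [52, 2048]], correction=False)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.pvalue == pytest.approx(p, rel=1e-10)

    def test_low_expected_flagged_but_returned(self):
        res = chi_squared_enrichment(1, 5, 0, 1000)
        assert res.low_expected
        assert np.isfinite(res.statistic)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_enrichment(0, 0, 5, 10)


class TestTagFraction:
    def test_all_tags_contain_member(self):
        tags = [make_tag("AGAAGA", tag_id=f"t{i}") for i in range(5)]
        assert tag_fraction_containing(tags, {"AGAAGA"}) == 1.0

    def test_no_tag_contains_any(self):
        tags = [make_tag("CCCCCC", tag_id=f"t{i}") for i in range(5)]
        assert tag_fraction_containing(tags, {"AGAAGA", "TTTTTT"}) == 0.0

    def test_empty_kmer_set_is_zero(self):
        assert tag_fraction_containing([make_tag("ACGT")], set()) == 0.0

    def test_empty_tags_rejected(self):
        with pytest.raises(ValueError):
            tag_fraction_containing([], {"AAA"})

    def test_vectorized_matches_per_tag_scan(self, rng):
        tags = [make_tag(random_seq(rng, int(rng.integers(10, 60))), tag_id=f"t{i}")
                for i in range(200)]
        vec = tag_fraction_all(tags, 3)
        for km in ("AGA", "GAA", "TTT", "CGC"):
            assert vec[kmer_index(km)] == pytest.approx(
                tag_fraction_containing(tags, {km})
            )


def test_rank_recovery_curve_consistency(small_dataset):
    """Curve points carry each k-mer's tag fraction and GAA flag, ordered by rank."""
    import clipmotif as cm

    df = cm.analyze_tags(small_dataset.tags, small_dataset.genome.values(),
                         small_dataset.transcript_sequences(), k=6)
    curve = rank_recovery_curve(df)
    assert len(curve) == 4**6
    assert list(curve["rank"]) == list(range(1, 4**6 + 1))
    merged = curve.merge(df[["kmer", "tag_fraction", "core_class"]], on="kmer")
    assert np.allclose(merged["tag_fraction_x"], merged["tag_fraction_y"])
    assert (curve["is_gaa"] == (curve["core_class"] == "GAA")).all()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=40), min_size=1, max_size=8),
       st.integers(min_value=1, max_value=6))
def test_count_kmers_property_matches_oracle(seqs, k):
    table = count_kmers(seqs, k)
    oracle = brute_force_counts([s.upper() for s in seqs], k)
    assert table.as_dict() == oracle
    assert table.total_windows == sum(oracle.values())
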