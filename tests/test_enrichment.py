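"""Exact-test enrichment with full-enumeration hypergeometric oracles."""
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_annotation
from tdmr.enrichment import (category_enrichment, downstream_fraction_test,
                             fisher_exact, flag_target_genes, make_result,
                             nuclear_mt_ratio, tf_target_enrichment)
from tdmr.errors import ValidationError


def enumeration_tail(k, n, K, N, direction="over"):
    """Oracle: exhaustive enumeration over all C(N, n) draws of the focal set
    from a background with K hits."""
    labels = [1] * K + [0] * (N - K)
    hit_count = 0
    for draw in combinations(range(N), n):
        hits = sum(labels[i] for i in draw)
        if (direction == "over" and hits >= k) or \
           (direction == "under" and hits <= k):
            hit_count += 1
    return Fraction(hit_count, comb(N, n))


class TestFisherExact:
    def test_worked_table(self):
        # 4-of-8 focal set, 3 hits inside, 4 hits total -> P(X>=3) = 17/70
        p = fisher_exact(3, 4, 4, 8, "over")
        assert p == pytest.approx(17 / 70, abs=1e-12)
        assert enumeration_tail(3, 4, 4, 8) == Fraction(17, 70)

    def test_set_equals_background_p_one(self):
        assert fisher_exact(5, 10, 5, 10, "over") == pytest.approx(1.0)

    def test_zero_hits_over_p_one(self):
        assert fisher_exact(0, 4, 0, 10, "over") == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(ValidationError):
            fisher_exact(5, 4, 6, 10)
        with pytest.raises(ValidationError):
            fisher_exact(3, 4, 2, 10)
        with pytest.raises(ValidationError):
            fisher_exact(0, 8, 7, 10)  # 8 misses in set, only 3 in background

    def test_bad_direction(self):
        with pytest.raises(ValidationError):
            fisher_exact(1, 2, 3, 6, "sideways")

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_property_matches_enumeration(self, data):
        N = data.draw(st.integers(2, 9))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        lo, hi = max(0, n - (N - K)), min(n, K)
        k = data.draw(st.integers(lo, hi))
        direction = data.draw(st.sampled_from(["over", "under"]))
        want = enumeration_tail(k, n, K, N, direction)
        assert fisher_exact(k, n, K, N, direction) == pytest.approx(
            float(want), abs=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_property_depleted_table_p_at_least_half(self, data):
        N = data.draw(st.integers(2, 40))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        lo, hi = max(0, n - (N - K)), min(n, K)
        ks = [k for k in range(lo, hi + 1) if Fraction(k, n) <= Fraction(K, N)]
        if not ks:
            return
        k = data.draw(st.sampled_from(ks))
        assert fisher_exact(k, n, K, N, "over") >= 0.5


class TestMakeResult:
    def test_fold_exact_rational_identity(self):
        r = make_result(3, 7, 10, 31)
        assert r.fold_exact * Fraction(10, 31) == Fraction(3, 7)

    def test_fold_value(self):
        r = make_result(4, 8, 5, 20)
        assert r.fold == pytest.approx(2.0)

    def test_p_in_unit_interval(self):
        r = make_result(2, 5, 9, 12, "under")
        assert 0 < r.p_value <= 1


class TestCategoryEnrichment:
    def _summary(self, hypo_genes, all_genes):
        return pd.DataFrame({
            "gene_id": all_genes,
            "is_nuclear_mt": True,
            "has_tdmr": True,
            "hypo_liver": [g in hypo_genes for g in all_genes]})

    def test_category_covering_all_genes(self):
        genes = [f"g{i}" for i in range(10)]
        ann = make_annotation([(g, "chrS", "+", 0, 0, 100, True, "metabolism")
                               for g in genes])
        res = category_enrichment(self._summary(set(genes[:4]), genes), ann,
                                  "liver")
        over = res[(res["category"] == "metabolism") & (res["direction"] == "over")]
        assert over["fold"].iloc[0] == pytest.approx(1.0)
        assert over["p_value"].iloc[0] == pytest.approx(1.0)

    def test_planted_category_enriched(self):
        genes = [f"g{i}" for i in range(12)]
        hypo = set(genes[:4])
        ann = make_annotation([
            (g, "chrS", "+", 0, 0, 100, True,
             "detox" if g in hypo else "ribosome") for g in genes])
        res = category_enrichment(self._summary(hypo, genes), ann, "liver")
        over = res[(res["category"] == "detox") & (res["direction"] == "over")]
        # all 4 detox genes inside the 4-gene hypo set out of 12
        assert over["fold"].iloc[0] == pytest.approx(3.0)
        want = enumeration_tail(4, 4, 4, 12)
        assert over["p_value"].iloc[0] == pytest.approx(float(want), abs=1e-12)

    def test_empty_hypo_set_error(self):
        genes = [f"g{i}" for i in range(5)]
        ann = make_annotation([(g, "chrS", "+", 0, 0, 100, True, "metabolism")
                               for g in genes])
        with pytest.raises(ValidationError):
            category_enrichment(self._summary(set(), genes), ann, "liver")


class TestFlagTargetGenes:
    def _gene(self, strand="+", tss=50_000, length=2000):
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length + 1, tss + 1
        return make_annotation([("gA", "chrS", strand, tss, start, end, True, "")])

    def _peaks(self, intervals):
        return pd.DataFrame(intervals, columns=["chrom", "start", "end"])

    def test_peak_at_tss(self):
        t = flag_target_genes(self._peaks([("chrS", 50_000, 50_001)]),
                              self._gene("+"))
        assert t == {"gA"}

    def test_peak_just_beyond_upstream_limit(self):
        t = flag_target_genes(self._peaks([("chrS", 39_999, 40_000)]),
                              self._gene("+"))
        assert t == set()

    def test_peak_at_upstream_limit(self):
        t = flag_target_genes(self._peaks([("chrS", 40_000, 40_001)]),
                              self._gene("+"))
        assert t == {"gA"}

    def test_downstream_of_three_prime(self):
        # + gene ends at 52_000; 1 kb grace ends at 53_000 (exclusive)
        assert flag_target_genes(self._peaks([("chrS", 52_999, 53_000)]),
                                 self._gene("+")) == {"gA"}
        assert flag_target_genes(self._peaks([("chrS", 53_000, 53_001)]),
                                 self._gene("+")) == set()

    def test_other_chromosome_ignored(self):
        t = flag_target_genes(self._peaks([("chr2", 50_000, 50_001)]),
                              self._gene("+"))
        assert t == set()

    def test_mirror_image_oracle(self):
        L = 1_000_000
        rng = np.random.default_rng(41)
        rows, mirrored = [], []
        for i in range(20):
            start = int(rng.integers(30_000, L - 30_000))
            end = start + int(rng.integers(500, 5000))
            strand = rng.choice(["+", "-"])
            tss = start if strand == "+" else end - 1
            tpe = end if strand == "+" else start
            rows.append((f"g{i}", "chrS", strand, tss, start, end, tpe, True, ""))
            m_strand = "-" if strand == "+" else "+"
            m_start, m_end = L - end, L - start
            m_tss = m_start if m_strand == "+" else m_end - 1
            m_tpe = m_end if m_strand == "+" else m_start
            mirrored.append((f"g{i}", "chrS", m_strand, m_tss, m_start, m_end,
                             m_tpe, True, ""))
        cols = ["gene_id", "chrom", "strand", "tss", "span_start", "span_end",
                "three_prime_end", "is_nuclear_mt", "categories"]
        ann1, ann2 = pd.DataFrame(rows, columns=cols), \
            pd.DataFrame(mirrored, columns=cols)
        starts = rng.integers(0, L - 200, 300)
        peaks1 = self._peaks([("chrS", int(s), int(s) + 150) for s in starts])
        peaks2 = self._peaks([("chrS", L - int(s) - 150, L - int(s))
                              for s in starts])
        assert flag_target_genes(peaks1, ann1) == flag_target_genes(peaks2, ann2)


class TestTfTargetEnrichment:
    def test_focal_equals_background_fold_one(self):
        genes = {f"g{i}" for i in range(20)}
        r = tf_target_enrichment({"g0", "g1", "g2"}, genes, genes)
        assert r.fold == pytest.approx(1.0)

    def test_all_targets_inside_focal_maximal_fold(self):
        background = {f"g{i}" for i in range(20)}
        focal = {f"g{i}" for i in range(5)}
        r = tf_target_enrichment(focal, focal, background)
        assert r.fold == pytest.approx(len(background) / len(focal))

    def test_empty_focal_error(self):
        with pytest.raises(ValidationError):
            tf_target_enrichment({"g0"}, set(), {"g0", "g1"})

    def test_focal_not_subset_error(self):
        with pytest.raises(ValidationError):
            tf_target_enrichment(set(), {"gX"}, {"g0"})


class TestDownstreamFractionTest:
    def _summary(self, a_down, a_up, b_down, b_up):
        rows = []
        for i in range(a_down):
            rows.append((f"a_d{i}", True, True, False, True))
        for i in range(a_up):
            rows.append((f"a_u{i}", True, True, False, False))
        for i in range(b_down):
            rows.append((f"b_d{i}", True, False, True, None, True))
        for i in range(b_up):
            rows.append((f"b_u{i}", True, False, True, None, False))
        df = pd.DataFrame(
            [r[:2] for r in rows], columns=["gene_id", "is_nuclear_mt"])
        df["hypo_liver"] = [r[2] for r in rows]
        df["hypo_brain"] = [r[3] for r in rows]
        df["hypo_liver_downstream"] = [bool(r[4]) if r[2] else False
                                       for r in rows]
        df["hypo_brain_downstream"] = [bool(r[5]) if len(r) > 5 else False
                                       for r in rows]
        return df

    def test_identical_fractions_p_at_least_half(self):
        s = self._summary(a_down=3, a_up=3, b_down=3, b_up=3)
        r = downstream_fraction_test(s, "liver", "brain")
        assert r.p_value >= 0.5

    def test_all_downstream_vs_none_enumeration(self):
        na, nb = 4, 5
        s = self._summary(a_down=na, a_up=0, b_down=0, b_up=nb)
        r = downstream_fraction_test(s, "liver", "brain")
        want = enumeration_tail(na, na, na, na + nb)
        assert want == Fraction(1, comb(na + nb, na))
        assert r.p_value == pytest.approx(float(want), abs=1e-12)

    def test_swapping_tissues_flips_direction(self):
        s = self._summary(a_down=4, a_up=1, b_down=1, b_up=4)
        ra = downstream_fraction_test(s, "liver", "brain")
        rb = downstream_fraction_test(s, "brain", "liver")
        assert ra.p_value < 0.5 < rb.p_value

    def test_empty_set_error(self):
        s = self._summary(a_down=2, a_up=0, b_down=0, b_up=0)
        s["hypo_brain"] = False
        with pytest.raises(ValidationError):
            downstream_fraction_test(s, "liver", "brain")


class TestNuclearMtRatio:
    def _summary(self, mt_flags, hypo_flags, down_flags=None):
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(mt_flags))],
            "is_nuclear_mt": mt_flags, "has_tdmr": hypo_flags,
            "hypo_liver": hypo_flags})
        df["hypo_liver_downstream"] = down_flags if down_flags is not None \
            else [False] * len(mt_flags)
        return df

    def test_all_nuclear_mt_both_one(self):
        s = self._summary([True] * 6, [True, False] * 3)
        r = nuclear_mt_ratio(s, "liver")
        assert r == {"all_genes": 1.0, "hypo_genes": 1.0}

    def test_no_hypo_calls_error(self):
        s = self._summary([True] * 4, [False] * 4)
        with pytest.raises(ValidationError):
            nuclear_mt_ratio(s, "liver")

    def test_only_mt_genes_carry_downstream_sites(self):
        mt = [True, True, False, False]
        down = [True, True, False, False]
        s = self._summary(mt, [True] * 4, down)
        r = nuclear_mt_ratio(s, "liver", downstream_only=True)
        assert r["hypo_genes"] == 1.0
        assert r["all_genes"] == 0.5
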