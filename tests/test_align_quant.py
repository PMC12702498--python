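"""Alignment, window construction, and quantification metrics."""

import math

import numpy as np
import pytest

from ampedit import (
    AlleleSpec,
    Read,
    align_read,
    build_be_quant_window,
    build_pe_quant_window,
    classify_indel_read,
    pathogenic_allele_correction,
    quality_filter,
    quantify,
)
from ampedit.align import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH, ReadAlignment
from ampedit.refs import AmpliconRef, GenotypeBaseline, GuideSite, QuantWindow
from conftest import exact_mixture_reads, random_amplicon_with_guide


def _read(seq, q=35):
    return Read("r", seq, (q,) * len(seq))


class TestQualityFilter:
    def test_all_above_threshold_retained(self):
        reads = [_read("ACGT", 35) for _ in range(5)]
        assert quality_filter(reads, 30) == reads

    def test_boundary_mean_just_below_dropped(self):
        # mean 29.9 < 30
        r = Read("r", "ACGTACGTAC", (30,) * 9 + (29,))
        assert r.mean_quality == pytest.approx(29.9)
        assert quality_filter([r], 30) == []

    def test_mixed_set_matches_brute_force(self):
        rng = np.random.default_rng(0)
        reads = [
            Read(f"r{i}", "ACGT" * 10, tuple(rng.integers(20, 41, 40)))
            for i in range(100)
        ]
        kept = quality_filter(reads, 30)
        expected = [r for r in reads if sum(r.qualities) / len(r.qualities) >= 30]
        assert kept == expected

    def test_empty_input_ok(self):
        assert quality_filter([], 30) == []


def gotoh_score(a, b):
    """Independent quadratic-time affine-gap global alignment score.

    Gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Iy[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + GAP_OPEN, Ix[i - 1][j] + GAP_EXTEND,
                           Iy[i - 1][j] + GAP_OPEN)
            Iy[i][j] = max(M[i][j - 1] + GAP_OPEN, Iy[i][j - 1] + GAP_EXTEND,
                           Ix[i][j - 1] + GAP_OPEN)
    return max(M[n][m], Ix[n][m], Iy[n][m])


class TestAlignRead:
    def test_identity_read(self, planted_amplicon):
        ref, _ = planted_amplicon
        aln = align_read(_read(ref.sequence), ref)
        assert aln.aligned
        assert aln.identity == 1.0
        assert aln.insertions == () and aln.deletions == () and aln.substitutions == ()

    def test_planted_deletion_recovered(self, planted_amplicon):
        ref, _ = planted_amplicon
        read = ref.sequence[:100] + ref.sequence[103:]
        aln = align_read(_read(read), ref)
        assert len(aln.deletions) == 1
        d0, d1 = aln.deletions[0]
        assert d1 - d0 == 3
        # homopolymer context can shift the placement by a base or two
        assert abs(d0 - 100) <= 3

    def test_planted_insertion_recovered(self, planted_amplicon):
        ref, _ = planted_amplicon
        read = ref.sequence[:100] + "TTAA" + ref.sequence[100:]
        aln = align_read(_read(read), ref)
        assert sum(len(s) for _, s in aln.insertions) == 4

    def test_score_matches_dp_oracle_on_random_50mers(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 50))
            b = "".join(rng.choice(list("ACGT"), 50))
            ref = AmpliconRef("r", a)
            assert align_read(b, ref).score == pytest.approx(gotoh_score(a, b))

    def test_low_identity_counted_unaligned(self, planted_amplicon):
        ref, _ = planted_amplicon
        junk = "A" * len(ref)
        aln = align_read(_read(junk), ref)
        assert not aln.aligned

    def test_empty_read_rejected(self, planted_amplicon):
        ref, _ = planted_amplicon
        with pytest.raises(ValueError):
            align_read("", ref)


class TestWindows:
    def test_single_guide_window(self):
        g = GuideSite(role="pegRNA", spacer="G" * 20, strand="+", start=83)
        assert g.nick_position == 100
        win = build_pe_quant_window([g])
        assert (win.start, win.end) == (90, 110)

    def test_two_nick_window_span(self):
        a = GuideSite(role="pegRNA", spacer="G" * 20, strand="+", start=83)   # nick 100
        b = GuideSite(role="ngRNA", spacer="G" * 20, strand="-", start=146)   # nick 149
        win = build_pe_quant_window([a, b])
        assert (win.start, win.end) == (90, 159)
        assert len(win) == 69

    def test_flap_rule_replaces_downstream_bound(self):
        a = GuideSite(role="pegRNA", spacer="G" * 20, strand="+", start=83)
        b = GuideSite(role="ngRNA", spacer="G" * 20, strand="-", start=146)
        win = build_pe_quant_window([a, b], flap_end=170)
        assert (win.start, win.end) == (90, 180)

    def test_flap_rule_upstream_bound(self):
        a = GuideSite(role="pegRNA", spacer="G" * 20, strand="-", start=97)  # nick 100
        win = build_pe_quant_window([a], flap_end=80)
        assert (win.start, win.end) == (70, 110)

    def test_no_guides_error(self):
        with pytest.raises(ValueError):
            build_pe_quant_window([])

    def test_mixed_amplicons_error(self):
        a = GuideSite(role="pegRNA", spacer="G" * 20, strand="+", start=80, amplicon_id="x")
        b = GuideSite(role="ngRNA", spacer="G" * 20, strand="+", start=90, amplicon_id="y")
        with pytest.raises(ValueError, match="amplicons"):
            build_pe_quant_window([a, b])

    def test_be_window_covers_protospacer(self):
        g = GuideSite(role="sgRNA", spacer="G" * 20, strand="+", start=60)
        win = build_be_quant_window(g)
        assert (win.start, win.end) == (60, 80)

    def test_be_window_minus_strand_same_interval(self):
        g = GuideSite(role="sgRNA", spacer="G" * 20, strand="-", start=60)
        assert build_be_quant_window(g) == QuantWindow(60, 80)

    def test_be_window_requires_20nt(self):
        g = GuideSite(role="sgRNA", spacer="G" * 19, strand="+", start=60)
        with pytest.raises(ValueError):
            build_be_quant_window(g)

    def test_be_window_clipped_with_warning(self):
        g = GuideSite(role="sgRNA", spacer="G" * 20, strand="+", start=60)
        with pytest.warns(UserWarning, match="clipped"):
            win = build_be_quant_window(g, amplicon_length=70)
        assert (win.start, win.end) == (60, 70)


def _aln(insertions=(), deletions=()):
    return ReadAlignment(
        score=0.0, identity=1.0, aligned=True, calls="A" * 200,
        insertions=tuple(insertions), deletions=tuple(deletions),
        substitutions=(),
    )


class TestIndelClassification:
    def test_deletion_inside_window_discarded(self):
        win = QuantWindow(90, 110)
        assert classify_indel_read(_aln(deletions=[(100, 101)]), win) == "discarded"

    def test_deletion_outside_window_retained(self):
        win = QuantWindow(90, 110)
        assert classify_indel_read(_aln(deletions=[(120, 125)]), win) == "retained"

    def test_insertion_at_boundary_discarded(self):
        win = QuantWindow(90, 110)
        assert classify_indel_read(_aln(insertions=[(90, "T")]), win) == "discarded"
        assert classify_indel_read(_aln(insertions=[(110, "T")]), win) == "discarded"
        assert classify_indel_read(_aln(insertions=[(111, "T")]), win) == "retained"

    def test_matches_interval_overlap_oracle(self):
        rng = np.random.default_rng(3)
        win = QuantWindow(80, 120)
        for _ in range(100):
            kind = rng.integers(0, 2)
            p = int(rng.integers(0, 190))
            if kind == 0:
                a = _aln(deletions=[(p, p + int(rng.integers(1, 8)))])
                d0, d1 = a.deletions[0]
                expect = d0 < win.end and d1 > win.start
            else:
                a = _aln(insertions=[(p, "T" * int(rng.integers(1, 4)))])
                expect = win.start <= p <= win.end
            got = classify_indel_read(a, win) == "discarded"
            assert got == expect


class TestMetrics:
    def test_no_indels_zero_pct(self, planted_amplicon):
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        reads = exact_mixture_reads(ref, [AlleleSpec("wt")], n_reads=1000)
        res = quantify(ref, reads, win)
        assert res.indel_pct == 0.0

    def test_indel_pct_80_of_1000(self, planted_amplicon):
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        mid = (win.start + win.end) // 2
        alleles = [
            AlleleSpec("wt", weight=920),
            AlleleSpec("del", indel=(mid, 3), weight=80),
        ]
        res = quantify(ref, exact_mixture_reads(ref, alleles, n_reads=1000), win)
        assert res.discarded == 80
        assert res.indel_pct == pytest.approx(8.0)

    def test_substitution_pct_planted(self, planted_amplicon):
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        pos = win.start + 5
        rb = ref.sequence[pos]
        ab = "ACGT"[("ACGT".index(rb) + 1) % 4]
        alleles = [
            AlleleSpec("wt", weight=980),
            AlleleSpec("sub", edits=((pos, rb, ab),), weight=20),
        ]
        res = quantify(ref, exact_mixture_reads(ref, alleles, n_reads=1000), win)
        assert res.substitution_pct() == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "mut_weight,wt_weight,expected_floor",
        [(2, 1, 33), (1, 2, 66), (1, 1, 50), (1, 0, 0)],
        ids=["triploid-2:1", "triploid-1:2", "het-1:1", "homozygous"],
    )
    def test_baseline_genotypes(self, planted_amplicon, mut_weight, wt_weight, expected_floor):
        """Error-free mixtures at fixed allele ratios recover the expected
        wild-type genotype percentage (floored to integer)."""
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        pos = guide.start + 10
        wt_base = ref.sequence[pos]
        mut_base = "ACGT"[("ACGT".index(wt_base) + 1) % 4]
        alleles = [AlleleSpec("mut", edits=((pos, wt_base, mut_base),), weight=mut_weight)]
        if wt_weight:
            alleles.append(AlleleSpec("wt", weight=wt_weight))
        res = quantify(ref, exact_mixture_reads(ref, alleles, n_reads=3000), win)
        assert math.floor(res.genotype_pct(pos, wt_base)) == expected_floor

    def test_genotype_outside_window_error(self, planted_amplicon):
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        reads = exact_mixture_reads(ref, [AlleleSpec("wt")], n_reads=10)
        res = quantify(ref, reads, win)
        with pytest.raises(ValueError, match="outside window"):
            res.genotype_pct(win.end + 1, "A")

    def test_indel_pct_missing_when_nothing_aligned(self, planted_amplicon):
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        res = quantify(ref, [], win)
        assert res.indel_pct is None
        assert res.substitution_pct() is None


class TestPathogenicAlleleCorrection:
    def _result_with_wt_pct(self, planted_amplicon, wt_frac):
        ref, guide = planted_amplicon
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        pos = guide.start + 10
        wt_base = ref.sequence[pos]
        mut_base = "ACGT"[("ACGT".index(wt_base) + 1) % 4]
        alleles = []
        if wt_frac > 0:
            alleles.append(AlleleSpec("wt", weight=wt_frac))
        if wt_frac < 1:
            alleles.append(AlleleSpec("mut", edits=((pos, wt_base, mut_base),), weight=1 - wt_frac))
        res = quantify(ref, exact_mixture_reads(ref, alleles, n_reads=2000), win)
        return res, pos, wt_base

    def test_no_change_from_heterozygous_baseline(self, planted_amplicon):
        res, pos, b = self._result_with_wt_pct(planted_amplicon, 0.5)
        assert pathogenic_allele_correction(res, GenotypeBaseline(2, 1), pos, b) == pytest.approx(0.0)

    def test_full_conversion(self, planted_amplicon):
        res, pos, b = self._result_with_wt_pct(planted_amplicon, 1.0)
        assert pathogenic_allele_correction(res, GenotypeBaseline(2, 1), pos, b) == pytest.approx(100.0)

    def test_formula_inversion_43pct(self, planted_amplicon):
        # 71.5% WT genotype at a 50% heterozygous baseline -> 43% correction
        res, pos, b = self._result_with_wt_pct(planted_amplicon, 0.715)
        corr = pathogenic_allele_correction(res, GenotypeBaseline(2, 1), pos, b)
        assert corr == pytest.approx(43.0, abs=0.1)

    def test_all_wt_baseline_error(self, planted_amplicon):
        res, pos, b = self._result_with_wt_pct(planted_amplicon, 1.0)
        with pytest.raises(ValueError, match="fully wild type"):
            pathogenic_allele_correction(res, GenotypeBaseline(2, 2), pos, b)


class TestInvariants:
    def test_conservation_and_normalization(self):
        ref, guide = random_amplicon_with_guide(21)
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        pos = guide.start + 5
        rb = ref.sequence[pos]
        ab = "ACGT"[("ACGT".index(rb) + 2) % 4]
        alleles = [
            AlleleSpec("wt", weight=60),
            AlleleSpec("sub", edits=((pos, rb, ab),), weight=30),
            AlleleSpec("del", indel=(pos, 2), weight=10),
        ]
        reads = exact_mixture_reads(ref, alleles, n_reads=400, seed=2, error_rate=0.002)
        res = quantify(ref, reads, win)
        assert res.retained + res.discarded == res.aligned_total
        assert res.aligned_total <= res.q_filtered_reads <= res.total_reads
        sums = res.nuc_pct.sum(axis=1)
        expected = 100.0 * res.retained / res.aligned_total
        assert np.allclose(sums, expected, atol=1e-9)

    def test_monotonicity_adding_indel_reads(self):
        ref, guide = random_amplicon_with_guide(22)
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        mid = (win.start + win.end) // 2
        last = -1.0
        for indel_w in (0, 5, 10, 20):
            alleles = [AlleleSpec("wt", weight=100)]
            if indel_w:
                alleles.append(AlleleSpec("del", indel=(mid, 2), weight=indel_w))
            res = quantify(ref, exact_mixture_reads(ref, alleles, n_reads=500), win)
            assert res.indel_pct >= last
            last = res.indel_pct

    def test_roundtrip_recovery_within_one_read(self):
        """Error-free exact-count mixtures recover planted fractions to 1/n."""
        ref, guide = random_amplicon_with_guide(23)
        win = build_pe_quant_window([guide], amplicon_length=len(ref))
        pos = guide.start + 8
        rb = ref.sequence[pos]
        ab = "ACGT"[("ACGT".index(rb) + 1) % 4]
        n = 500
        alleles = [
            AlleleSpec("wt", weight=0.37),
            AlleleSpec("mut", edits=((pos, rb, ab),), weight=0.63),
        ]
        res = quantify(ref, exact_mixture_reads(ref, alleles, n_reads=n, seed=9), win)
        assert abs(res.genotype_pct(pos, rb) / 100 - 0.37) <= 1.0 / n
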