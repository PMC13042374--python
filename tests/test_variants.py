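"""Candidate calling, the filter cascade, and origin classification."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from freesv.core import ReferenceGenome
from freesv.variants import (
    FilterResources,
    PileupColumn,
    VariantCall,
    apply_filter_cascade,
    call_candidates,
    classify_paired,
    classify_pbmc_only,
    error_qual,
    pileup_from_fragments,
    retained,
)
from .conftest import make_fragment


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Independent exact binomial tail P(X >= k) via math.comb."""
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


class TestErrorQual:
    @pytest.mark.parametrize("k,n", [(1, 10), (4, 32), (10, 30), (2, 100)])
    def test_matches_exact_binomial_oracle(self, k, n):
        eps = 1e-3
        expected = -10.0 * math.log10(binom_tail_oracle(k, n, eps / 3))
        assert error_qual(k, n, eps) == pytest.approx(min(expected, 255.0), rel=1e-9)

    def test_zero_alt_is_zero(self):
        assert error_qual(0, 30) == 0.0

    def test_capped_at_255(self):
        assert error_qual(50, 60) == 255.0


def col(chrom, pos, ref, **counts):
    return PileupColumn(chrom, pos, ref, dict(counts))


class TestCallCandidates:
    def test_emseq_thymine_at_ref_c_not_candidate(self):
        calls = call_candidates([col("chr1", 10, "C", C=28, T=4)], mode="emseq")
        assert calls == []

    def test_emseq_non_thymine_alt_allowed(self):
        (c,) = call_candidates([col("chr1", 10, "C", C=28, A=4)], mode="emseq")
        assert (c.ref, c.alt, c.alt_count) == ("C", "A", 4)

    def test_emseq_reverse_strand_mirror(self):
        assert call_candidates([col("chr1", 10, "G", G=28, A=4)], mode="emseq") == []
        (c,) = call_candidates([col("chr1", 10, "G", G=28, T=4)], mode="emseq")
        assert c.alt == "T"

    def test_no_alt_observations_no_call(self):
        assert call_candidates([col("chr1", 10, "A", A=30)]) == []

    def test_qual_matches_binomial_oracle(self):
        (c,) = call_candidates([col("chr1", 10, "A", A=20, G=10)], error_rate=1e-3)
        expected = -10.0 * math.log10(binom_tail_oracle(10, 30, 1e-3 / 3))
        assert c.qual == pytest.approx(min(expected, 255.0), rel=1e-9)

    def test_unsorted_input_fails(self):
        cols = [col("chr1", 20, "A", A=10, G=5), col("chr1", 10, "A", A=10, G=5)]
        with pytest.raises(ValueError, match="sorted"):
            call_candidates(cols)

    def test_below_min_depth_skipped(self):
        assert call_candidates([col("chr1", 10, "A", A=1, G=1)], min_depth=4) == []

    def test_multiallelic_count_recorded(self):
        (c,) = call_candidates([col("chr1", 10, "A", A=20, G=6, T=3)])
        assert c.alt == "G" and c.n_nonref_alleles == 2


def _call(pos=100, chrom="chr1", ref="A", alt="G", qual=60.0, depth=30,
          alt_count=5, n_alts=1):
    return VariantCall(chrom, pos, ref=ref, alt=alt, qual=qual, depth=depth,
                       alt_count=alt_count, n_nonref_alleles=n_alts)


def _resources(**kwargs):
    defaults = dict(autosomes=frozenset({"chr1", "chr2"}))
    defaults.update(kwargs)
    return FilterResources(**defaults)


def cascade_oracle(calls, resources, coverage, window=1, min_qual=30.0,
                   max_af=0.001):
    """Independent brute-force filter evaluation (exhaustive re-check)."""
    cov_values = sorted(coverage[(c.chrom, c.pos)] for c in calls)
    cut = np.quantile(np.array(cov_values, dtype=float),
                      1 - resources.coverage_quantile_cut)
    kept = []
    for c in calls:
        if len(c.ref) != 1 or len(c.alt) != 1:
            continue
        if c.chrom not in resources.autosomes:
            continue
        if c.n_nonref_alleles > 1:
            continue
        if c.qual < min_qual:
            continue
        if any(o is not c and o.chrom == c.chrom and abs(o.pos - c.pos) <= window
               for o in calls):
            continue
        if resources.in_blacklist(c.chrom, c.pos):
            continue
        if coverage[(c.chrom, c.pos)] > cut:
            continue
        af = resources.max_population_af(c.chrom, c.pos, c.alt)
        cosmic = (c.chrom, c.pos, c.alt) in resources.cosmic_set
        if af > max_af and not cosmic:
            continue
        kept.append((c.chrom, c.pos, c.alt))
    return kept


class TestFilterCascade:
    def test_qual_boundary_30_passes(self):
        calls = [_call(pos=100, qual=29.0), _call(pos=500, qual=30.0)]
        cov = {("chr1", 100): 10, ("chr1", 500): 10}
        out = apply_filter_cascade(calls, _resources(), cov)
        assert "low_qual" in out[0].filter_flags
        assert out[1].passed

    def test_common_polymorphism_removed_unless_cosmic(self):
        af = {("chr1", 100, "G"): 0.002, ("chr1", 500, "G"): 0.002}
        cosmic = frozenset({("chr1", 500, "G")})
        calls = [_call(pos=100), _call(pos=500)]
        cov = {("chr1", 100): 10, ("chr1", 500): 10}
        out = apply_filter_cascade(calls, _resources(population_af=af,
                                                     cosmic_set=cosmic), cov)
        assert "common_polymorphism" in out[0].filter_flags
        assert out[1].passed

    def test_af_boundary_exactly_point1_percent_passes(self):
        af = {("chr1", 100, "G"): 0.001}
        cov = {("chr1", 100): 10}
        out = apply_filter_cascade([_call(pos=100)], _resources(population_af=af), cov)
        assert out[0].passed

    def test_adjacent_candidates_both_removed(self):
        calls = [_call(pos=100), _call(pos=101, ref="C", alt="T"), _call(pos=500)]
        cov = {("chr1", 100): 10, ("chr1", 101): 10, ("chr1", 500): 10}
        out = apply_filter_cascade(calls, _resources(), cov)
        assert "continuous" in out[0].filter_flags
        assert "continuous" in out[1].filter_flags
        assert out[2].passed

    def test_non_autosome_and_multiallelic_flagged(self):
        calls = [_call(chrom="chrX", pos=100), _call(pos=200, n_alts=2)]
        cov = {("chrX", 100): 10, ("chr1", 200): 10}
        out = apply_filter_cascade(calls, _resources(), cov)
        assert "non_autosome" in out[0].filter_flags
        assert "multiallelic" in out[1].filter_flags

    def test_missing_coverage_names_locus(self):
        with pytest.raises(KeyError, match="chr1:100"):
            apply_filter_cascade([_call(pos=100)], _resources(), {})

    def test_scripted_set_matches_bruteforce_oracle(self):
        rng = random.Random(42)
        calls, cov = [], {}
        for i in range(12):
            pos = rng.choice([100 + i * 7, 100 + i * 7 + 1])
            c = _call(
                chrom=rng.choice(["chr1", "chr2", "chrX"]),
                pos=pos,
                qual=rng.choice([10.0, 29.9, 30.0, 80.0]),
                n_alts=rng.choice([1, 1, 1, 2]),
            )
            calls.append(c)
            cov[(c.chrom, c.pos)] = rng.choice([5, 10, 20, 500])
        resources = _resources(
            blacklist=[("chr1", 120, 140)],
            population_af={(c.chrom, c.pos, c.alt): rng.choice([0.0, 0.002])
                           for c in calls},
            cosmic_set=frozenset({(calls[3].chrom, calls[3].pos, calls[3].alt)}),
        )
        out = apply_filter_cascade(calls, resources, cov)
        got = [(c.chrom, c.pos, c.alt) for c in retained(out)]
        assert got == cascade_oracle(calls, resources, cov)

    def test_order_independent_and_flags_complete(self):
        rng = random.Random(7)
        calls = [_call(pos=100 + 5 * i, qual=rng.choice([20.0, 60.0])) for i in range(8)]
        cov = {(c.chrom, c.pos): rng.choice([10, 30]) for c in calls}
        baseline = {(c.chrom, c.pos) for c in retained(
            apply_filter_cascade(calls, _resources(), cov))}
        for perm in itertools.islice(itertools.permutations(calls), 0, 24, 5):
            out = apply_filter_cascade(list(perm), _resources(), cov)
            assert {(c.chrom, c.pos) for c in retained(out)} == baseline
            for c in out:
                assert c.passed or len(c.filter_flags) >= 1


class TestInjectionRecovery:
    """Cascade recall on synthetic pileups with known truth."""

    def test_recall_and_error_attribution(self):
        rng = np.random.default_rng(3)
        depth, eps = 100, 1e-3
        n_loci, n_variants = 400, 60
        variant_pos = set(rng.choice(np.arange(n_loci), n_variants, replace=False))
        columns, truth, error_pos = [], set(), set()
        for i in range(n_loci):
            pos = 1000 + 3 * i  # spaced: no adjacency among loci
            is_var = i in variant_pos
            vaf = rng.uniform(0.10, 0.40) if is_var else 0.0
            alt_n = rng.binomial(depth, vaf)
            err_n = rng.binomial(depth - alt_n, eps)
            counts = {"A": depth - alt_n - err_n, "G": alt_n}
            if err_n:
                counts["T"] = err_n
                error_pos.add(pos)
            if is_var:
                truth.add(pos)
            columns.append(PileupColumn("chr1", pos, "A", counts))
        calls = call_candidates(columns, error_rate=eps)
        cov = {(c.chrom, c.pos): depth for c in calls}
        out = apply_filter_cascade(calls, _resources(), cov)
        kept = retained(out)
        kept_pos = {c.pos for c in kept}
        # variants whose alt support survived binomial sampling
        recall = len(kept_pos & truth) / len(truth)
        assert recall >= 0.95
        for c in kept:
            assert c.pos in truth or c.pos in error_pos


class TestClassifyPaired:
    def test_ch_derived(self):
        pbmc = {("chr1", 100): col("chr1", 100, "A", A=40, G=5)}
        tumor = {("chr1", 100): col("chr1", 100, "A", A=60)}
        (v,) = classify_paired(pbmc, tumor)
        assert (v.origin_class, v.alt, v.ref) == ("CH_derived", "G", "A")

    def test_minor_support_below_3_unclassified(self):
        pbmc = {("chr1", 100): col("chr1", 100, "A", A=40, G=2)}
        tumor = {("chr1", 100): col("chr1", 100, "A", A=60)}
        assert classify_paired(pbmc, tumor) == []

    def test_tumor_derived(self):
        pbmc = {("chr1", 100): col("chr1", 100, "A", A=50)}
        tumor = {("chr1", 100): col("chr1", 100, "A", A=30, C=25)}
        (v,) = classify_paired(pbmc, tumor)
        assert (v.origin_class, v.alt) == ("tumor_derived", "C")

    def test_low_coverage_and_single_sample_loci_skipped(self):
        pbmc = {("chr1", 100): col("chr1", 100, "A", A=20, G=5),
                ("chr1", 200): col("chr1", 200, "A", A=40, G=5)}
        tumor = {("chr1", 100): col("chr1", 100, "A", A=60)}
        assert classify_paired(pbmc, tumor) == []  # 100 underpowered, 200 unmatched


class TestClassifyPbmcOnly:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 900, "T": 45}, "CH_derived"),  # MAF 4.8%
            ({"A": 990, "T": 10}, None),  # MAF 1.0% below band
            ({"A": 600, "T": 400}, None),  # MAF 40%: ordinary heterozygote
        ],
    )
    def test_maf_band(self, counts, expected):
        pbmc = {("chr1", 100): col("chr1", 100, "A", **counts)}
        out = classify_pbmc_only(pbmc)
        if expected is None:
            assert out == []
        else:
            assert out[0].origin_class == expected

    def test_coverage_floor(self):
        pbmc = {("chr1", 100): col("chr1", 100, "A", A=190, T=10)}
        assert classify_pbmc_only(pbmc) == []  # depth 200 < 300


class TestPileupFromFragments:
    def test_implicit_reference_support(self, toy_reference):
        # three fragments over the same locus; one records an alt call
        ref_base = toy_reference.base("chrT", 150)
        alt = "G" if ref_base != "G" else "C"
        frags = [
            make_fragment("chrT", 100, 260, name="a", base_calls=[(150, alt, 37)]),
            make_fragment("chrT", 110, 270, name="b"),
            make_fragment("chrT", 120, 280, name="c"),
        ]
        columns, coverage = pileup_from_fragments(frags, toy_reference)
        (c,) = columns
        assert c.pos == 151
        assert c.counts[alt] == 1
        assert c.counts[ref_base] == 2
        assert coverage[("chrT", 151)] == 3

    def test_low_quality_calls_excluded_but_counted_in_depth(self, toy_reference):
        ref_base = toy_reference.base("chrT", 150)
        alt = "G" if ref_base != "G" else "C"
        frags = [make_fragment("chrT", 100, 260, name="a",
                               base_calls=[(150, alt, 10)])]
        columns, _ = pileup_from_fragments(frags, toy_reference)
        assert columns == []  # only observation fails the base-quality bar
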