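"""Mut/Wt partition, size, motifs, diversity, E-index, nucleosome context."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freesv.core import ReferenceGenome, revcomp
from freesv.fragmentomics import (
    EndModel,
    breakpoint_motifs,
    build_end_model,
    diff,
    e_index,
    end_motifs,
    frac_short,
    motif_diversity,
    nucleosome_end_fraction,
    partition_by_allele,
)
from freesv.variants import VariantCall
from .conftest import make_fragment


def _locus(chrom, pos1, ref, alt):
    return VariantCall(chrom, pos1, ref=ref, alt=alt, qual=60.0, depth=30,
                       alt_count=5)


class TestPartition:
    def test_alt_base_goes_to_mut(self):
        loci = [_locus("c", 101, "A", "G")]  # pos0 = 100
        frag = make_fragment("c", 50, 200, base_calls=[(100, "G", 37)])
        part = partition_by_allele([frag], loci)
        assert part.mut_fragments == [frag] and part.wt_fragments == []

    def test_ref_base_goes_to_wt(self):
        loci = [_locus("c", 101, "A", "G")]
        frag = make_fragment("c", 50, 200, base_calls=[(100, "A", 37)])
        part = partition_by_allele([frag], loci)
        assert part.wt_fragments == [frag]

    def test_multi_locus_fragment_excluded(self):
        loci = [_locus("c", 101, "A", "G"), _locus("c", 151, "C", "T")]
        frag = make_fragment("c", 50, 200, base_calls=[(100, "G", 37), (150, "C", 37)])
        part = partition_by_allele([frag], loci)
        assert part.excluded_multi == 1
        assert part.mut_fragments == [] and part.wt_fragments == []

    def test_no_observation_or_third_allele_dropped(self):
        loci = [_locus("c", 101, "A", "G")]
        frags = [make_fragment("c", 50, 200, name="noobs"),
                 make_fragment("c", 50, 200, name="third", base_calls=[(100, "T", 37)])]
        part = partition_by_allele(frags, loci)
        assert part.excluded_other == 2

    def test_scripted_fragments_match_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        loci = [_locus("c", int(p), "A", "G") for p in [101, 301, 501, 701, 901]]
        loci_pos0 = {c.pos - 1: c for c in loci}
        frags = []
        for i in range(100):
            start = int(rng.integers(0, 900))
            frag = make_fragment("c", start, start + int(rng.integers(80, 260)),
                                 name=f"f{i}")
            for pos0 in loci_pos0:
                if frag.interval.contains(pos0) and rng.random() < 0.8:
                    base = rng.choice(["A", "G", "C"], p=[0.5, 0.4, 0.1])
                    frag.base_calls.append((pos0, str(base), 37))
            frags.append(frag)
        part = partition_by_allele(frags, loci)
        # independent exhaustive per-fragment check
        exp_mut, exp_wt, exp_multi = [], [], 0
        for frag in frags:
            hits = [p for p in loci_pos0 if frag.interval.contains(p)]
            if len(hits) > 1:
                exp_multi += 1
                continue
            if not hits:
                continue
            obs = dict((p, b) for p, b, _ in frag.base_calls)
            base = obs.get(hits[0])
            if base == "G":
                exp_mut.append(frag.name)
            elif base == "A":
                exp_wt.append(frag.name)
        assert [f.name for f in part.mut_fragments] == exp_mut
        assert [f.name for f in part.wt_fragments] == exp_wt
        assert part.excluded_multi == exp_multi


class TestFracShort:
    def test_boundary_150_inclusive(self):
        frags = [make_fragment("c", 0, 150), make_fragment("c", 0, 151)]
        assert frac_short(frags) == 0.5

    def test_all_long_zero(self):
        assert frac_short([make_fragment("c", 0, 166)] * 3) == 0.0

    def test_empty_undefined(self):
        assert frac_short([]) is None

    def test_mixture_matches_direct_count(self):
        rng = np.random.default_rng(3)
        lengths = np.where(rng.random(1000) < 0.3,
                           rng.normal(140, 10, 1000), rng.normal(170, 8, 1000))
        lengths = np.maximum(np.rint(lengths).astype(int), 60)
        frags = [make_fragment("c", 0, int(l)) for l in lengths]
        assert frac_short(frags) == (lengths <= 150).sum() / 1000


class TestMotifs:
    def test_u_end_motif_direct_lookup(self):
        ref = ReferenceGenome({"c": "TTCCGATTTTTTTTTTTTTTTTTTTTTTTTTTGGGT"})
        frag = make_fragment("c", 2, 30)
        vec, _ = end_motifs([frag], ref)
        from freesv.fragmentomics import MOTIFS_256
        got = {MOTIFS_256[i] for i in np.flatnonzero(vec)}
        # U motif = seq[2:6] = CCGA; D motif = revcomp(seq[26:30])
        assert "CCGA" in got
        assert revcomp(ref.fetch("c", 26, 30)) in got

    def test_ccca_at_both_ends_fraction_one(self):
        #            0123456789...
        seq = "TTCCCATTTTTTTTTTTTTTTTTTTTTTTGGGT" + "A" * 10
        # U end at 2: CCCA; D end so that revcomp(d-3..d) == CCCA => TGGG
        seq = "TTCCCATTTTTTTTTTTTTTTTTTTTTTTTGGGAAAAA"
        ref = ReferenceGenome({"c": seq})
        d = seq.index("TGGG") + 3
        frag = make_fragment("c", 2, d + 1)
        vec, frac = end_motifs([frag], ref)
        assert frac == 1.0
        assert vec.sum() == pytest.approx(1.0)

    def test_breakpoint_ct_cut_cc(self):
        # reference ...C T | C C A...  with U end at the cut
        seq = "AAAACTCCAT" + "T" * 30
        ref = ReferenceGenome({"c": seq})
        frag = make_fragment("c", 6, 36)  # starts at first C after CT
        vec, frac = breakpoint_motifs([frag], ref)
        from freesv.fragmentomics import MOTIFS_256
        got = {MOTIFS_256[i] for i in np.flatnonzero(vec)}
        assert "CTCC" in got

    def test_no_ctcc_when_cuts_after_aa_before_tt(self):
        seq = "A" * 20 + "TT" + "T" * 20 + "AA" + "A" * 20
        ref = ReferenceGenome({"c": seq})
        frag = make_fragment("c", 20, 40)
        _, frac = breakpoint_motifs([frag], ref)
        assert frac == 0.0

    def test_simulated_set_matches_direct_tally(self, toy_reference):
        rng = np.random.default_rng(9)
        frags = [make_fragment("chrT", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(10, 1800, 500),
                                 rng.integers(80, 190, 500))]
        vec, frac = end_motifs(frags, toy_reference)
        bvec, bfrac = breakpoint_motifs(frags, toy_reference)
        # independent tally by direct slicing
        seq = toy_reference.sequences["chrT"]
        end_tally, bp_tally = Counter(), Counter()
        for f in frags:
            end_tally[seq[f.u_end:f.u_end + 4]] += 1
            end_tally[revcomp(seq[f.d_end - 3:f.d_end + 1])] += 1
            bp_tally[seq[f.u_end - 2:f.u_end + 2]] += 1
            bp_tally[revcomp(seq[f.d_end - 1:f.d_end + 3])] += 1
        from freesv.fragmentomics import MOTIFS_256
        n = sum(end_tally.values())
        expected = np.array([end_tally.get(m, 0) / n for m in MOTIFS_256])
        assert np.allclose(vec, expected)
        assert frac == pytest.approx(end_tally.get("CCCA", 0) / n)
        nb = sum(bp_tally.values())
        assert np.allclose(bvec, np.array([bp_tally.get(m, 0) / nb for m in MOTIFS_256]))
        assert bfrac == pytest.approx(bp_tally.get("CTCC", 0) / nb)

    def test_contig_edge_termini_skipped(self):
        ref = ReferenceGenome({"c": "ACGTACGTAC"})
        frag = make_fragment("c", 8, 10)  # U motif would run off the end
        vec, _ = end_motifs([frag], ref)
        assert vec is None or vec.sum() == pytest.approx(1.0)


class TestMotifDiversity:
    def test_uniform_is_one(self):
        assert motif_diversity(np.full(256, 1 / 256)) == pytest.approx(1.0)

    def test_single_motif_is_zero(self):
        v = np.zeros(256)
        v[0] = 1.0
        assert motif_diversity(v) == 0.0

    def test_two_motif_closed_form(self):
        v = np.zeros(256)
        v[0] = v[1] = 0.5
        assert motif_diversity(v) == pytest.approx(math.log(2) / math.log(256))

    def test_negative_entry_rejected(self):
        v = np.full(256, 1 / 256)
        v[0] = -v[0]
        v[1] += 2 / 256
        with pytest.raises(ValueError):
            motif_diversity(v)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_on_random_distributions(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.dirichlet(np.full(256, 0.3))
        assert 0.0 <= motif_diversity(v) <= 1.0


class TestEndModel:
    def test_shared_u_end_counted_twice(self):
        frags = [make_fragment("c", 100, 260), make_fragment("c", 100, 280)]
        model = build_end_model(frags)
        assert model.u_counts[("c", 100)] == 2

    def test_single_fragment_two_ends(self):
        model = build_end_model([make_fragment("c", 5, 100)])
        assert model.total_panel_ends == 2

    def test_scripted_panel_matches_tally(self):
        rng = np.random.default_rng(4)
        frags = [make_fragment("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 5000, 300), rng.integers(60, 200, 300))]
        model = build_end_model(frags)
        u_tally, d_tally = Counter(), Counter()
        for f in frags:
            u_tally[("c", f.u_end)] += 1
            d_tally[("c", f.d_end)] += 1
        assert model.u_counts == dict(u_tally)
        assert model.d_counts == dict(d_tally)

    def test_empty_panel_fails(self):
        with pytest.raises(ValueError):
            build_end_model([])

    def test_tsv_roundtrip(self, tmp_path):
        frags = [make_fragment("c", 10, 100), make_fragment("c", 10, 150)]
        model = build_end_model(frags)
        path = tmp_path / "em.tsv"
        model.to_tsv(path)
        back = EndModel.from_tsv(path)
        assert back.u_counts == model.u_counts
        assert back.d_counts == model.d_counts


class TestEIndex:
    def test_formula_identity(self):
        # every fragment's U end has raw count a=3, D end count b=2
        panel = [make_fragment("c", 100, 200)] * 3 + [make_fragment("c", 150, 200)] * 2
        # panel: u_counts[100]=3, u_counts[150]=2; d_counts[199]=5
        model = build_end_model(panel)
        sample = [make_fragment("c", 100, 150)]  # u=100 (count 3), d=149 (count 0)
        s = model.scale
        assert e_index(sample, model) == pytest.approx(s * 3)
        sample2 = [make_fragment("c", 150, 200)]  # u=150 (2), d=199 (5)
        assert e_index(sample2, model) == pytest.approx(s * 7)

    def test_absent_positions_contribute_zero(self):
        model = build_end_model([make_fragment("c", 10, 100)])
        assert e_index([make_fragment("c", 500, 700)], model) == 0.0

    def test_empty_sample_undefined(self):
        model = build_end_model([make_fragment("c", 10, 100)])
        assert e_index([], model) is None

    def test_scripted_fragments_match_bruteforce_sum(self):
        rng = np.random.default_rng(6)
        panel = [make_fragment("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 2000, 400), rng.integers(60, 200, 400))]
        model = build_end_model(panel)
        sample = [make_fragment("c", int(s), int(s) + int(l))
                  for s, l in zip(rng.integers(0, 2000, 200), rng.integers(60, 200, 200))]
        # brute force per-fragment sum
        u_tally, d_tally = Counter(), Counter()
        for f in panel:
            u_tally[f.u_end] += 1
            d_tally[f.d_end] += 1
        scale = 1e6 / (2 * len(panel))
        expected = np.mean([scale * (u_tally.get(f.u_end, 0) + d_tally.get(f.d_end, 0))
                            for f in sample])
        assert e_index(sample, model) == pytest.approx(expected, abs=1e-12)

    def test_order_invariance_and_raw_mode_scaling(self):
        rng = np.random.default_rng(12)
        panel = [make_fragment("c", int(s), int(s) + 100) for s in rng.integers(0, 500, 50)]
        model = build_end_model(panel)
        sample = [make_fragment("c", int(s), int(s) + 100) for s in rng.integers(0, 500, 30)]
        assert e_index(sample, model) == e_index(list(reversed(sample)), model)
        raw = e_index(sample, model, normalized=False)
        assert e_index(sample, model) == pytest.approx(raw * model.scale)


class TestNucleosomeEndFraction:
    def test_all_ends_at_centers(self):
        centers = {"c": np.array([100, 300])}
        frags = [make_fragment("c", 100, 301)]  # u=100, d=300
        frac, dist = nucleosome_end_fraction(frags, centers)
        assert frac == 100.0
        assert list(dist) == [0, 0]

    def test_inclusive_boundary_at_50(self):
        centers = {"c": np.array([1000])}
        inside = make_fragment("c", 1050, 1300)  # u = center + 50
        outside = make_fragment("c", 1051, 1300)  # u = center + 51
        frac_in, _ = nucleosome_end_fraction([inside], centers)
        frac_out, _ = nucleosome_end_fraction([outside], centers)
        assert frac_in == 50.0  # u inside, d far outside
        assert frac_out == 0.0

    def test_signed_distance_negative_upstream(self):
        centers = {"c": np.array([1000])}
        frag = make_fragment("c", 980, 1011)  # u=980 (-20), d=1010 (+10)
        _, dist = nucleosome_end_fraction([frag], centers)
        assert sorted(dist.tolist()) == [-20, 10]

    def test_tie_breaks_toward_smaller_coordinate(self):
        centers = {"c": np.array([100, 140])}
        frag = make_fragment("c", 120, 400)  # u=120 equidistant from both
        _, dist = nucleosome_end_fraction([frag], centers)
        assert dist[0] == 20  # measured against center 100, not 140

    def test_chromosome_without_centers_excluded(self):
        centers = {"c": np.array([100])}
        frags = [make_fragment("other", 0, 100), make_fragment("c", 100, 200)]
        frac, dist = nucleosome_end_fraction(frags, centers)
        assert len(dist) == 2  # only ends of the annotated chromosome

    def test_scripted_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(31)
        centers = {"c": np.sort(rng.choice(20_000, 80, replace=False))}
        frags = [make_fragment("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 19_000, 300), rng.integers(60, 200, 300))]
        frac, dist = nucleosome_end_fraction(frags, centers)
        # exhaustive nearest-neighbour scan
        inside = 0
        exp_dist = []
        for f in frags:
            for end in (f.u_end, f.d_end):
                best = min(centers["c"], key=lambda c: (abs(end - c), c))
                exp_dist.append(end - best)
                if abs(end - best) <= 50:
                    inside += 1
        assert dist.tolist() == exp_dist
        assert frac == pytest.approx(100.0 * inside / (2 * len(frags)))

    def test_invariant_under_global_shift(self):
        rng = np.random.default_rng(13)
        centers = {"c": np.sort(rng.choice(10_000, 40, replace=False))}
        frags = [make_fragment("c", int(s), int(s) + 120) for s in rng.integers(0, 9000, 100)]
        frac, _ = nucleosome_end_fraction(frags, centers)
        shift = 5000
        frags2 = [make_fragment("c", f.interval.start + shift, f.interval.end + shift)
                  for f in frags]
        centers2 = {"c": centers["c"] + shift}
        frac2, _ = nucleosome_end_fraction(frags2, centers2)
        assert frac == frac2


class TestDiff:
    def test_subtraction(self):
        assert diff(0.30, 0.18) == pytest.approx(0.12)

    def test_equal_inputs_zero(self):
        assert diff(0.5, 0.5) == 0.0

    def test_undefined_propagates(self):
        assert diff(None, 0.5) is None
        assert diff(0.5, None) is None
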