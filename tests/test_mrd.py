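import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctdyn.synthetic import simulate_read_families

from ctdyn.mrd import (BackgroundErrorDB, ConsensusRead, PlasmaCallResult,
                       ReadFamily, StructuralError, TissueVariant, TumorProfile,
                       VariantCall, assess_ctdna_positivity, build_dcs,
                       build_sscs, call_tissue_mutations, candidate_calls,
                       consensus_pileup, log_ctdna_level,
                       mean_vaf_from_log_level, polish_variants)



def fam(reads, umi=("AAA", "CCC"), orient="AB", pos=100):
    return ReadFamily(contig="chr1", position=pos, umi_a=umi[0], umi_b=umi[1],
                      orientation=orient, reads=tuple({pos: b} for b in reads))


class TestBuildSSCS:
    def test_two_identical_reads_emit_one_sscs(self):
        out = build_sscs([fam("TT")])
        assert len(out) == 1
        assert out[0].alleles[100] == "T"
        assert out[0].n_reads == 2

    def test_singleton_family_dropped(self):
        assert build_sscs([fam("T")]) == []

    def test_majority_vote_five_reads(self):
        # brute-force majority of CCCCT is C
        reads = "CCCCT"
        counts = {b: reads.count(b) for b in set(reads)}
        majority = max(counts, key=counts.get)
        out = build_sscs([fam(reads)])
        assert out[0].alleles[100] == majority == "C"

    def test_exact_tie_masked(self):
        out = build_sscs([fam("CCTT")])
        assert out[0].alleles[100] == "N"


class TestBuildDCS:
    def test_transposed_pair_merges(self):
        a = build_sscs([fam("TT", ("AAA", "CCC"), "AB")])[0]
        b = build_sscs([fam("TT", ("CCC", "AAA"), "BA")])[0]
        out = build_dcs([a, b])
        assert len(out) == 1
        assert out[0].level == "DCS"
        assert out[0].alleles[100] == "T"

    def test_merge_symmetric_in_order(self):
        a = build_sscs([fam("TT", ("AAA", "CCC"), "AB")])[0]
        b = build_sscs([fam("TT", ("CCC", "AAA"), "BA")])[0]
        r1 = build_dcs([a, b])
        a2 = build_sscs([fam("TT", ("AAA", "CCC"), "AB")])[0]
        b2 = build_sscs([fam("TT", ("CCC", "AAA"), "BA")])[0]
        r2 = build_dcs([b2, a2])
        assert r1[0].alleles == r2[0].alleles
        assert r1[0].support == r2[0].support

    def test_unpartnered_sscs_retained_flagged(self):
        a = build_sscs([fam("TT")])[0]
        out = build_dcs([a])
        assert len(out) == 1
        assert out[0].level == "SSCS"
        assert out[0].single_strand_flag

    def test_strand_disagreement_masked(self):
        # enumerate agree/disagree cases
        for ba, bb, expect in [("T", "T", "T"), ("T", "C", "N"),
                               ("C", "T", "N"), ("C", "C", "C")]:
            a = build_sscs([fam(ba * 2, ("AAA", "CCC"), "AB")])[0]
            b = build_sscs([fam(bb * 2, ("CCC", "AAA"), "BA")])[0]
            assert build_dcs([a, b])[0].alleles[100] == expect

    def test_three_claimants_structural_error(self):
        members = [build_sscs([fam("TT", ("AAA", "CCC"), "AB")])[0]
                   for _ in range(3)]
        with pytest.raises(StructuralError):
            build_dcs(members)

    def test_non_sscs_input_rejected(self):
        a = build_sscs([fam("TT")])[0]
        d = build_dcs([a, build_sscs([fam("TT", ("CCC", "AAA"), "BA")])[0]])[0]
        with pytest.raises(StructuralError):
            build_dcs([d])

    def test_dcs_count_bound(self):
        rng = np.random.default_rng(0)
        fams = simulate_read_families(0.3, 50, seed=1).families
        sscs = build_sscs(fams)
        out = build_dcs(sscs)
        n_dcs = sum(1 for c in out if c.level == "DCS")
        n_single = sum(1 for c in out if c.level == "SSCS")
        assert n_dcs <= len(sscs) // 2
        assert 2 * n_dcs + n_single == len(sscs)
        assert all(c.position == 1000 for c in out)


class TestPolish:
    def db(self, rate=1e-5):
        return BackgroundErrorDB(rates={("chr1", 100, "C>T"): rate})

    def call(self, k, n):
        return VariantCall("chr1", 100, "C", "T", depth=n, mutant_reads=k,
                           duplex_support=k, sscs_support=0)

    def test_zero_mutant_reads_rejected(self):
        out = polish_variants([self.call(0, 30000)], self.db())
        assert out == []

    def test_thirty_of_thirty_thousand_retained(self):
        c = self.call(30, 30000)
        out = polish_variants([c], self.db(1e-5), alpha=0.01)
        # oracle: exact binomial tail P(X >= 30 | n=30000, p=1e-5)
        tail = stats.binom.sf(29, 30000, 1e-5)
        assert tail < 1e-10
        assert out == [c]
        assert c.polish_p == pytest.approx(tail)

    def test_mutant_fraction_at_db_rate_rejected(self):
        # 30 mutant / 3e4 reads vs rate 1e-3 -> tail approx 0.5
        c = self.call(30, 30000)
        out = polish_variants([c], self.db(1e-3), alpha=0.01)
        assert out == []
        assert 0.4 < c.polish_p < 0.6

    def test_support_criterion(self):
        db = self.db(1e-6)
        weak = VariantCall("chr1", 100, "C", "T", depth=30000, mutant_reads=5,
                           duplex_support=0, sscs_support=1)
        strong = VariantCall("chr1", 100, "C", "T", depth=30000,
                             mutant_reads=5, duplex_support=1, sscs_support=0)
        assert polish_variants([weak], db) == []
        assert polish_variants([strong], db) == [strong]

    def test_missing_db_entry_uses_floor(self, caplog):
        db = BackgroundErrorDB(rates={})
        c = self.call(5, 30000)
        with caplog.at_level("WARNING"):
            out = polish_variants([c], db)
        assert "rate floor" in caplog.text
        assert c.polish_p == pytest.approx(stats.binom.sf(4, 30000, 1e-6))
        assert out == [c]

    def test_polish_p_recorded_on_rejects(self):
        c = self.call(1, 1000)
        polish_variants([c], self.db(1e-3))
        assert not math.isnan(c.polish_p)


class TestTissueCalling:
    def test_hotspot_thresholds(self):
        v = TissueVariant("chr17", 7578406, "C", "T", vaf=0.012,
                          supporting_reads=6, cosmic_count=100)
        assert len(call_tissue_mutations([v])) == 1

    def test_non_hotspot_vaf_below_two_percent_rejected(self):
        v = TissueVariant("chr1", 200, "G", "A", vaf=0.015,
                          supporting_reads=6, cosmic_count=0)
        assert len(call_tissue_mutations([v])) == 0

    def test_zero_vaf_rejected(self):
        v = TissueVariant("chr1", 200, "G", "A", vaf=0.0,
                          supporting_reads=10, cosmic_count=100)
        assert len(call_tissue_mutations([v])) == 0

    @pytest.mark.parametrize("vaf,reads,cosmic,kept", [
        (0.01, 5, 20, True),    # hotspot at exact thresholds
        (0.01, 4, 20, False),   # hotspot, too few reads
        (0.009, 5, 20, False),  # hotspot, VAF below 1%
        (0.02, 6, 0, True),     # non-hotspot at exact thresholds
        (0.02, 5, 0, False),
        (0.05, 6, 19, True),    # 19 COSMIC cases is not a hotspot
    ])
    def test_threshold_grid(self, vaf, reads, cosmic, kept):
        v = TissueVariant("chr1", 1, "A", "T", vaf=vaf,
                          supporting_reads=reads, cosmic_count=cosmic)
        assert (len(call_tissue_mutations([v])) == 1) is kept


class TestPositivity:
    def profile(self, n=1):
        muts = [TissueVariant("chr17", 7578406 + i, "C", "T", vaf=0.1,
                              supporting_reads=20, cosmic_count=50)
                for i in range(n)]
        return TumorProfile(patient="P1", mutations=muts)

    def passing_call(self, pos, k, n):
        c = VariantCall("chr17", pos, "C", "T", depth=n, mutant_reads=k,
                        duplex_support=k)
        c.passed = True
        return c

    def test_single_passing_read_positive(self):
        res = assess_ctdna_positivity([self.passing_call(7578406, 1, 10000)],
                                      self.profile())
        assert res.positive
        assert len(res.detected) == 1

    def test_no_detection_negative_with_zero_vafs(self):
        res = assess_ctdna_positivity([], self.profile(2))
        assert not res.positive
        assert res.mean_vaf == 0.0
        assert res.max_vaf == 0.0

    def test_mean_and_max_vaf(self):
        calls = [self.passing_call(7578406, 20, 10000),   # VAF 0.002
                 self.passing_call(7578407, 40, 10000)]   # VAF 0.004
        res = assess_ctdna_positivity(calls, self.profile(2))
        assert res.mean_vaf == pytest.approx((0.002 + 0.004) / 2)
        assert res.max_vaf == pytest.approx(0.004)

    def test_tracked_mode_includes_undetected_zeros(self):
        calls = [self.passing_call(7578406, 30, 10000)]
        res = assess_ctdna_positivity(calls, self.profile(3))
        assert res.mean_vaf == pytest.approx(0.003 / 3)
        res_det = assess_ctdna_positivity(calls, self.profile(3),
                                          mean_mode="detected")
        assert res_det.mean_vaf == pytest.approx(0.003)

    def test_empty_profile_unevaluable(self):
        res = assess_ctdna_positivity([], TumorProfile("P2", []))
        assert res.unevaluable
        assert not res.positive

    @given(st.permutations(range(4)))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance(self, perm):
        calls = [self.passing_call(7578406 + i, 10 * (i + 1), 10000)
                 for i in range(4)]
        shuffled = [calls[i] for i in perm]
        a = assess_ctdna_positivity(calls, self.profile(4))
        b = assess_ctdna_positivity(shuffled, self.profile(4))
        assert a.positive == b.positive
        assert a.mean_vaf == b.mean_vaf
        assert [m.position for m in a.detected] == \
            [m.position for m in b.detected]


class TestLogCtdnaLevel:
    def test_zero_maps_to_zero(self):
        assert log_ctdna_level(0.0) == 0.0

    def test_one_ppm(self):
        assert log_ctdna_level(1e-6) == pytest.approx(math.log(2), rel=1e-12)

    def test_paper_scale_value(self):
        # ln((0.0034 + 1e-6)/1e-6) = ln(3401)
        assert log_ctdna_level(0.0034) == pytest.approx(math.log(3401.0),
                                                        rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_ctdna_level(-0.1)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_and_nonnegative(self, v):
        y = log_ctdna_level(v)
        assert y >= 0.0
        assert mean_vaf_from_log_level(y) == pytest.approx(v, abs=1e-12)


class TestReadFamilySimulator:
    def test_zero_error_rate_reads_match_truth(self):
        fs = simulate_read_families(1.0, 30, error_rate=0.0, seed=2)
        for f in fs.families:
            assert all(r[1000] == "T" for r in f.reads)

    def test_high_vaf_family_fraction(self):
        # binomial CI oracle: observed mutant-family fraction near 0.5
        fs = simulate_read_families(0.5, 10000, error_rate=0.0, seed=3,
                                    duplex_fraction=0.0)
        frac = np.mean([f.reads[0][1000] == "T" for f in fs.families])
        sd = math.sqrt(0.25 / 10000)
        assert abs(frac - 0.5) < 3 * sd

    def test_error_rate_calibration(self):
        fs = simulate_read_families(0.0, 4000, reads_per_family=1,
                                    error_rate=1e-3, seed=4,
                                    duplex_fraction=0.0)
        mism = np.mean([f.reads[0][1000] != "C" for f in fs.families])
        sd = math.sqrt(1e-3 * (1 - 1e-3) / 4000)
        assert abs(mism - 1e-3) < 3 * sd + 1e-12

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            simulate_read_families(1.5, 10)
        with pytest.raises(ValueError):
            simulate_read_families(0.5, 10, error_rate=0.5)


class TestEndToEndPipeline:
    def test_detection_at_moderate_vaf(self):
        fs = simulate_read_families(0.02, 500, reads_per_family=3,
                                    error_rate=1e-3, seed=5)
        consensus = build_dcs(build_sscs(fs.families))
        calls = candidate_calls(consensus, [("chr1", 1000, "C", "T")])
        db = BackgroundErrorDB(rates={("chr1", 1000, "C>T"): 1e-5})
        kept = polish_variants(calls, db)
        assert len(kept) == 1
        assert abs(kept[0].vaf - 0.02) < 0.02

    def test_pileup_masks_do_not_count(self):
        c = ConsensusRead(level="DCS", contig="chr1", position=5,
                          alleles={5: "N"}, support={"AB": 2, "BA": 2})
        pile = consensus_pileup([c], "chr1", 5)
        assert pile["depth"] == 0
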