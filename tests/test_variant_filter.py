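import itertools

import numpy as np
import pytest
from scipy import stats

from haplodnm.callable_genome import CallableSet
from haplodnm.core_io import (
    CALLER_HAPLOTYPE,
    CALLER_PILEUP,
    ConversionMask,
    DepthTrack,
    SampleCall,
    VariantObservation,
)
from haplodnm.variant_filter import (
    dnm_filter,
    group_shared_dnms,
    merge_caller_calls,
    pzm_filter,
    vaf_test,
)

MO, FA, O1 = "mother", "father", "o1"


def obs(contig="c1", pos=500, ref="A", alt="G", qual=400.0, caller=CALLER_PILEUP,
        off_gt=(1, 1), off_dp=30, off_ad=None, mo_dp=40, fa_dp=40,
        mo_ad=None, fa_ad=None, off=O1):
    if off_ad is None:
        off_ad = (0, off_dp) if off_gt == (1, 1) else (off_dp // 2, off_dp - off_dp // 2)
    return VariantObservation(contig, pos, ref, (alt,), qual, caller, {
        MO: SampleCall((0, 0), mo_dp, mo_ad or (mo_dp, 0)),
        FA: SampleCall((0, 0), fa_dp, fa_ad or (fa_dp, 0)),
        off: SampleCall(off_gt, off_dp, off_ad),
    })


def cset(contig="c1", length=1000, unphased=False):
    cs = CallableSet(O1)
    if unphased:
        cs.unphased_intervals[contig] = [(100, length - 100)]
        cs.unphased_contig_lengths[contig] = length
    else:
        cs.phased_intervals[contig] = [(100, length - 100)]
    return cs


PARENTS = {"c1": "maternal", "c2": "paternal"}
EMPTY_MASK = ConversionMask([])


def run_dnm(observations, callable_set_=None, gts=None, indels=None, mask=EMPTY_MASK, **kw):
    return dnm_filter(observations, callable_set_ or cset(), gts or {}, indels or set(),
                      mask, offspring_id=O1, mother_id=MO, father_id=FA,
                      contig_parents=PARENTS, **kw)


class TestMergeCallerCalls:
    def test_union_on_normal_contigs(self):
        a, b = obs(caller=CALLER_PILEUP), obs(caller=CALLER_HAPLOTYPE)
        merged = merge_caller_calls([a], [b], set())
        assert len(merged) == 2 and {m.caller for m in merged} == {CALLER_PILEUP, CALLER_HAPLOTYPE}

    def test_pileup_dropped_on_high_similarity_contig(self):
        merged = merge_caller_calls([obs()], [], {"c1"})
        assert merged == []

    def test_expected_multiset_from_overlap_structure(self):
        pile = [obs(contig="c1", pos=p) for p in (1, 2, 3)]
        hap = [obs(contig="c1", pos=p, caller=CALLER_HAPLOTYPE) for p in (2, 3, 4)]
        high = set()
        merged = merge_caller_calls(pile, hap, high)
        key = sorted((m.pos, m.caller) for m in merged)
        assert key == [(1, CALLER_PILEUP), (2, CALLER_HAPLOTYPE), (2, CALLER_PILEUP),
                       (3, CALLER_HAPLOTYPE), (3, CALLER_PILEUP), (4, CALLER_HAPLOTYPE)]


class TestDnmCriteria:
    def test_clean_candidate_passes_all_seven(self):
        recs = run_dnm([obs()])
        assert len(recs) == 1
        r = recs[0]
        assert (r.contig_id, r.pos, r.ref_base, r.alt_base, r.origin) == (
            "c1", 500, "A", "G", "maternal")

    def test_qual_threshold_scoped_to_pileup_caller(self):
        assert run_dnm([obs(qual=200.0, caller=CALLER_PILEUP)]) == []
        assert len(run_dnm([obs(qual=200.0, caller=CALLER_HAPLOTYPE)])) == 1

    def test_indel_flank_boundary_exclusive_at_20(self):
        indel_at = {("c1", 515)}
        assert run_dnm([obs(pos=500)], indels=indel_at) == []          # 15 bp away
        assert len(run_dnm([obs(pos=494)], indels=indel_at)) == 1      # 21 bp away
        assert run_dnm([obs(pos=495)], indels=indel_at) == []          # exactly 20

    def test_outside_callable_rejected(self):
        assert run_dnm([obs(pos=50)]) == []

    def test_heterozygous_offspring_rejected(self):
        assert run_dnm([obs(off_gt=(0, 1))]) == []

    def test_depth_thresholds_strict(self):
        assert run_dnm([obs(off_dp=10)]) == []
        assert run_dnm([obs(mo_dp=5)]) == []
        assert len(run_dnm([obs(off_dp=11, mo_dp=6)])) == 1
        # the paternal depth does not gate a maternal-contig candidate
        assert len(run_dnm([obs(fa_dp=0)])) == 1

    def test_parent_with_three_alt_alleles_rejected(self):
        o = VariantObservation("c1", 500, "A", ("C", "G", "T"), 400.0, CALLER_PILEUP, {
            MO: SampleCall((0, 0), 40, (30, 3, 4, 3)),
            FA: SampleCall((0, 0), 40, (40, 0, 0, 0)),
            O1: SampleCall((2, 2), 30, (0, 0, 30, 0)),
        })
        assert run_dnm([o]) == []

    def test_conversion_mask_rejects(self):
        assert run_dnm([obs()], mask=ConversionMask([("c1", 500)])) == []

    def test_het_sibling_rejects(self):
        gts = {("c1", 500): {"o2": (0, 1)}}
        assert run_dnm([obs()], gts=gts) == []
        gts_hom = {("c1", 500): {"o2": (1, 1)}}
        assert len(run_dnm([obs()], gts=gts_hom)) == 1

    def test_unknown_contig_is_error(self):
        with pytest.raises(KeyError):
            run_dnm([obs(contig="c9")])

    def test_unphased_contig_yields_unphased_origin(self):
        recs = dnm_filter([obs(caller=CALLER_HAPLOTYPE)], cset(unphased=True), {}, set(),
                          EMPTY_MASK, offspring_id=O1, mother_id=MO, father_id=FA,
                          contig_parents=PARENTS)
        assert recs[0].origin == "unphased"

    def test_filters_are_order_independent_conjunction(self, rng):
        """The retained set equals an independent per-criterion conjunction."""
        mask = ConversionMask([("c1", p) for p in range(400, 420)])
        indels = {("c1", 700)}
        gts = {("c1", p): {"o2": (0, 1)} for p in range(550, 560)}
        sites = []
        for _ in range(300):
            sites.append(obs(
                pos=int(rng.integers(0, 1000)),
                qual=float(rng.choice([150, 250, 400])),
                caller=str(rng.choice([CALLER_PILEUP, CALLER_HAPLOTYPE])),
                off_gt=(1, 1) if rng.random() < 0.8 else (0, 1),
                off_dp=int(rng.integers(5, 60)),
                mo_dp=int(rng.integers(0, 60)),
            ))
        got = {(r.contig_id, r.pos) for r in
               run_dnm(sites, gts=gts, indels=indels, mask=mask)}
        expected = set()
        cs = cset()
        for o in sites:
            checks = [
                cs.contains(o.contig_id, o.pos),
                o.samples[O1].genotype == (1, 1) and o.samples[O1].total_depth > 10,
                o.samples[MO].total_depth > 5,
                o.caller != CALLER_PILEUP or o.qual >= 220,
                all(abs(o.pos - ip) > 20 for (_, ip) in indels),
                (o.contig_id, o.pos) not in mask,
                all(g != (0, 1) for g in gts.get((o.contig_id, o.pos), {}).values()),
            ]
            if all(checks):
                expected.add((o.contig_id, o.pos))
        assert got == expected


class TestSharedDnms:
    def _rec(self, off, pos=500, alt="G"):
        from haplodnm.variant_filter import DnmRecord
        return DnmRecord(off, "c1", pos, "A", alt, "maternal")

    def test_two_siblings_form_one_group(self):
        recs = group_shared_dnms([self._rec("o1"), self._rec("o2")])
        gids = {r.shared_group_id for r in recs}
        assert len(gids) == 1 and None not in gids

    def test_unique_records_get_no_group(self):
        recs = group_shared_dnms([self._rec("o1", 100), self._rec("o2", 200)])
        assert all(r.shared_group_id is None for r in recs)

    def test_different_alt_not_grouped(self):
        recs = group_shared_dnms([self._rec("o1", alt="G"), self._rec("o2", alt="T")])
        assert all(r.shared_group_id is None for r in recs)

    def test_each_sharing_offspring_keeps_a_record(self):
        recs = group_shared_dnms([self._rec(o) for o in ("o1", "o2", "o3")])
        assert len(recs) == 3
        assert len({r.offspring_id for r in recs}) == 3


class TestVafTest:
    def test_null_value_gives_half(self):
        assert vaf_test(25, 100) == pytest.approx(0.5, abs=0.01)

    def test_matches_r_prop_test_values(self):
        # reference values from R: prop.test(x, n, p=0.25, alternative="greater")
        assert vaf_test(30, 100) == pytest.approx(0.1493488, rel=1e-5)
        assert vaf_test(35, 100) == pytest.approx(0.01412018, rel=1e-5)
        assert vaf_test(120, 200) == pytest.approx(3.737834e-30, rel=1e-5)

    def test_decisions_agree_with_exact_binomial(self):
        for n in (20, 50, 100, 200):
            for k in range(0, n + 1, max(1, n // 25)):
                approx = vaf_test(k, n) > 0.05
                exact = stats.binomtest(k, n, 0.25, alternative="greater").pvalue > 0.05
                if approx != exact:
                    # disagreement allowed only in a narrow boundary band
                    assert abs(vaf_test(k, n) - 0.05) < 0.03
        assert vaf_test(10, 200) > 0.9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vaf_test(1, 0)
        with pytest.raises(ValueError):
            vaf_test(10, 5)


class TestPzmFilter:
    def _run(self, observations, partner_dp=30.0, alt_depths=None, **kw):
        tracks = {"c2": DepthTrack("c2", O1, [0], [1000], [partner_dp])}
        return pzm_filter(
            observations, cset(), {}, alt_depths or {}, EMPTY_MASK, set(),
            O1, MO, FA, PARENTS, {"c1": "c2"}, tracks, **kw)

    def test_low_vaf_het_candidate_retained(self):
        o = obs(off_gt=(0, 1), off_dp=30, off_ad=(25, 5))
        (r,) = self._run([o])
        assert r.vaf == pytest.approx(5 / 60)
        assert r.p_value_vs_quarter > 0.05

    def test_high_vaf_candidate_rejected(self):
        o = obs(off_gt=(0, 1), off_dp=40, off_ad=(10, 30))
        assert self._run([o]) == []  # VAF 30/70 ~ 0.43, significantly > 0.25

    def test_sibling_with_three_alt_reads_rejects(self):
        o = obs(off_gt=(0, 1), off_dp=30, off_ad=(25, 5))
        assert self._run([o], alt_depths={("c1", 500): {"o2": 3}}) == []
        assert len(self._run([o], alt_depths={("c1", 500): {"o2": 2}})) == 1

    def test_parent_with_three_alt_reads_rejects(self):
        o = obs(off_gt=(0, 1), off_dp=30, off_ad=(25, 5), mo_ad=(37, 3))
        assert self._run([o]) == []

    def test_unphased_region_excluded(self):
        tracks = {"c2": DepthTrack("c2", O1, [0], [1000], [30.0])}
        o = obs(off_gt=(0, 1), off_dp=30, off_ad=(25, 5), caller=CALLER_HAPLOTYPE)
        recs = pzm_filter([o], cset(unphased=True), {}, {}, EMPTY_MASK, set(),
                          O1, MO, FA, PARENTS, {"c1": "c2"}, tracks)
        assert recs == []

    def test_missing_partner_drops_with_warning(self):
        o = obs(off_gt=(0, 1), off_dp=30, off_ad=(25, 5))
        tracks = {}
        with pytest.warns(UserWarning, match="no allelic counterpart"):
            recs = pzm_filter([o], cset(), {}, {}, EMPTY_MASK, set(),
                              O1, MO, FA, PARENTS, {}, tracks)
        assert recs == []
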