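import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haplodnm.core_io import PafRecord
from haplodnm.rates import (
    FOLDED_CLASSES,
    alpha_estimate,
    classify_dnm_records,
    context_of,
    context_rates,
    effective_population_size,
    false_negative_rate,
    mutation_rate,
    mutation_spectrum,
    origin_contrast,
    project_annotation,
    substitution_class,
)
from haplodnm.variant_filter import DnmRecord


class TestFnr:
    def test_printed_rate_from_illustrative_counts(self):
        assert false_negative_rate(952, 1000) == pytest.approx(0.048)

    def test_perfect_detection(self):
        assert false_negative_rate(100, 100) == 0.0

    def test_detected_exceeding_simulated_is_error(self):
        with pytest.raises(ValueError):
            false_negative_rate(11, 10)


class TestMutationRate:
    def test_published_study_inputs(self):
        # 242 DNMs over 104 offspring x 414.8 Mb average callable, FNR 4.8%
        est = mutation_rate(242, 104 * 414.8e6, fnr=0.048)
        assert est.mu == pytest.approx(5.89e-9, rel=1e-3)

    def test_zero_count(self):
        est = mutation_rate(0, 1e9, 0.0)
        assert est.mu == 0.0 and est.ci_low == 0.0 and est.ci_high > 0

    def test_rate_times_denominator_recovers_count_exactly(self):
        for n, L in ((1, 1e6), (242, 4.3e10), (7, 12345678)):
            assert mutation_rate(n, L, 0.0).mu * L == pytest.approx(n, rel=1e-12)

    def test_ci_matches_chi_square_quantile_oracle(self):
        n, L, fnr = 242, 104 * 414.8e6, 0.048
        est = mutation_rate(n, L, fnr)
        denom = L * (1 - fnr)
        lo = stats.chi2.ppf(0.025, 2 * n) / 2 / denom
        hi = stats.chi2.ppf(0.975, 2 * n + 2) / 2 / denom
        assert est.ci_low == pytest.approx(lo) and est.ci_high == pytest.approx(hi)
        assert est.ci_low <= est.mu <= est.ci_high

    def test_invalid_fnr(self):
        with pytest.raises(ValueError):
            mutation_rate(10, 1e6, 1.0)


class TestAlpha:
    def test_published_counts(self):
        est = alpha_estimate(n_paternal=108, n_maternal=96)
        assert round(est.alpha_raw, 2) == 1.12

    def test_equal_counts_equal_callable(self):
        est = alpha_estimate(n_paternal=50, n_maternal=50,
                             per_parent_callable_bp={"paternal": 1e9, "maternal": 1e9})
        assert est.alpha_raw == 1.0 and est.alpha_corrected == 1.0

    def test_shared_dnm_counts(self):
        est = alpha_estimate(n_paternal=33, n_maternal=15)
        assert est.alpha_raw == pytest.approx(2.2)

    def test_callable_correction_scales_ratio(self):
        est = alpha_estimate(n_paternal=100, n_maternal=100,
                             per_parent_callable_bp={"paternal": 2e9, "maternal": 1e9})
        assert est.alpha_corrected == pytest.approx(0.5)

    def test_records_interface_excludes_unphased(self):
        recs = [DnmRecord("o1", "c", i, "A", "G", origin)
                for i, origin in enumerate(["paternal"] * 3 + ["maternal"] * 2 + ["unphased"])]
        est = alpha_estimate(recs)
        assert (est.n_paternal, est.n_maternal) == (3, 2)

    def test_zero_maternal_is_undefined(self):
        est = alpha_estimate(n_paternal=5, n_maternal=0)
        assert math.isnan(est.alpha_raw)

    def test_ci_brackets_point_estimate(self):
        est = alpha_estimate(n_paternal=108, n_maternal=96)
        assert est.ci_low < est.alpha_raw < est.ci_high


class TestSubstitutionClass:
    @pytest.mark.parametrize("ref,alt,left,right,expected", [
        ("C", "T", "A", "G", "CpG>TpG"),
        ("G", "A", "C", "A", "CpG>TpG"),     # folded CpG
        ("C", "T", "A", "A", "C>T"),
        ("T", "G", None, None, "A>C"),       # folded
        ("A", "G", "C", "C", "A>G"),
        ("G", "C", "T", "T", "C>G"),
        ("T", "A", "G", "G", "A>T"),
    ])
    def test_examples(self, ref, alt, left, right, expected):
        assert substitution_class(ref, alt, left, right) == expected

    def test_non_acgt_base_rejected(self):
        with pytest.raises(ValueError):
            substitution_class("N", "A", None, None)

    def test_folding_is_involutive(self):
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                once = substitution_class(ref, alt, None, None)
                r2, a2 = once.split(">")
                assert substitution_class(r2, a2, None, None) == once

    def test_spectrum_proportions_sum_to_one(self, rng):
        recs = []
        seq = "ACGTACGTGG" * 10
        for i in range(1, 80):
            ref = seq[i]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            recs.append(DnmRecord("o1", "c", i, ref, alt, "maternal"))
        classify_dnm_records(recs, {"c": seq})
        spec = mutation_spectrum(recs)
        assert spec["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert spec["count"].sum() == len(recs)
        assert list(spec["class"]) == list(FOLDED_CLASSES)


class TestAnnotationProjection:
    def test_contig_inside_single_exon(self):
        paf = [PafRecord("ctg", 500, 0, 500, "+", "chr1", 10000, 2000, 2500, 490, 500, 60)]
        ctx = {"chr1": [(1000, 5000, "exonic")]}
        out = project_annotation(paf, ctx)
        assert out["ctg"] == [(0, 500, "exonic")]

    def test_unaligned_contig_is_unannotated(self):
        out = project_annotation([], {"chr1": [(0, 100, "exonic")]})
        assert context_of("ctg", 50, out) == "unannotated"

    def test_overlapping_reference_contexts_rejected(self):
        with pytest.raises(ValueError):
            project_annotation([], {"chr1": [(0, 100, "exonic"), (50, 150, "intronic")]})

    def test_positions_match_per_base_liftover_oracle(self, rng):
        ref_len = 2000
        labels = ["exonic", "intronic", "intergenic"]
        bounds = sorted(rng.choice(np.arange(1, ref_len), size=5, replace=False))
        ivs, start = [], 0
        for i, b in enumerate(list(bounds) + [ref_len]):
            ivs.append((start, int(b), labels[i % 3]))
            start = int(b)
        paf = []
        for i, (qs, ts, ln, strand) in enumerate(
                [(0, 100, 400, "+"), (0, 700, 300, "-"), (50, 1500, 350, "+")]):
            paf.append(PafRecord(f"ctg{i}", qs + ln + 50, qs, qs + ln, strand,
                                 "chr1", ref_len, ts, ts + ln, ln - 5, ln, 60))
        out = project_annotation(paf, {"chr1": ivs})

        def ref_label(p):
            for s, e, lab in ivs:
                if s <= p < e:
                    return lab
            return "unannotated"

        for rec in paf:
            for q in range(rec.qstart, rec.qend):
                if rec.strand == "+":
                    t = rec.tstart + (q - rec.qstart)
                else:
                    t = rec.tend - 1 - (q - rec.qstart)
                assert context_of(rec.qname, q, out) == ref_label(t), (rec.qname, q)


class TestContextRates:
    def _recs(self, counts):
        recs = []
        i = 0
        for ctx, n in counts.items():
            for _ in range(n):
                recs.append(DnmRecord("o1", "c", i, "A", "G", "maternal", context=ctx))
                i += 1
        return recs

    def test_single_context_equals_global_rate(self):
        recs = self._recs({"exonic": 10})
        df = context_rates(recs, {"exonic": 1e6}, fnr=0.1)
        global_rate = 10 / (1e6 * 0.9)
        assert df.loc[df.context == "exonic", "rate"].item() == pytest.approx(global_rate)

    def test_weighted_mean_of_context_rates_is_global_rate(self):
        recs = self._recs({"exonic": 5, "intronic": 20, "intergenic": 30})
        denoms = {"exonic": 2e5, "intronic": 1e6, "intergenic": 2e6}
        fnr = 0.05
        df = context_rates(recs, denoms, fnr)
        weighted = (df["rate"] * df["callable_bp"]).sum() / df["callable_bp"].sum()
        assert weighted == pytest.approx(55 / (sum(denoms.values()) * (1 - fnr)))

    def test_uniform_spiking_shows_no_context_difference(self, rng):
        denoms = {"exonic": 5e5, "intronic": 1.5e6, "intergenic": 3e6}
        total_bp = sum(denoms.values())
        n = 200
        ps = np.array([v / total_bp for v in denoms.values()])
        counts = rng.multinomial(n, ps)
        recs = self._recs(dict(zip(denoms, (int(c) for c in counts))))
        df = context_rates(recs, denoms, fnr=0.0)
        assert df.attrs["p_value"] > 0.01


class TestNe:
    def test_published_inputs(self):
        mu = mutation_rate(242, 104 * 414.8e6, 0.048).mu
        ne = effective_population_size(0.0397, mu)
        assert ne.ne == pytest.approx(1_684_375, rel=1e-3)

    def test_pi_equal_four_mu_gives_one(self):
        assert effective_population_size(4e-8, 1e-8).ne == pytest.approx(1.0)

    def test_formula_identity_on_grid(self, rng):
        for _ in range(50):
            pi = float(rng.uniform(1e-4, 0.1))
            mu = float(rng.uniform(1e-10, 1e-7))
            assert effective_population_size(pi, mu).ne == pytest.approx(pi / (4 * mu))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_population_size(0.0, 1e-9)


class TestOriginContrast:
    def test_balanced_table(self):
        orr, p = origin_contrast([[10, 10], [10, 10]])
        assert orr == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_against_hypergeometric_enumeration(self):
        table = [[33, 15], [75, 81]]
        _, p = origin_contrast(table)
        # independent oracle: enumerate hypergeometric tables with fixed margins
        a, b = table[0]
        c, d = table[1]
        r1, c1, n = a + b, a + c, a + b + c + d

        def prob(x):
            return (math.comb(c1, x) * math.comb(n - c1, r1 - x)) / math.comb(n, r1)

        p0 = prob(a)
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        p_exact = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p0 * (1 + 1e-9))
        assert p == pytest.approx(p_exact, rel=1e-6)

    def test_transpose_symmetry(self, rng):
        for _ in range(20):
            t = rng.integers(0, 40, size=(2, 2))
            _, p1 = origin_contrast(t)
            _, p2 = origin_contrast(t.T)
            assert p1 == pytest.approx(p2)

    def test_zero_margin_convention(self):
        orr, p = origin_contrast([[0, 0], [5, 8]])
        assert p == 1.0 and math.isnan(orr)
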