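import numpy as np
import pytest
from scipy import stats

from haplodnm.core_io import NON_BUBBLE
from haplodnm.inheritance import INHERITED
from haplodnm.simulate import (
    SimConfig,
    make_segments,
    place_no_variant_intervals,
    simulate_parent,
    simulate_pedigree,
    simulate_snp_positions,
)

TINY = dict(genome_length_bp=400_000, n_no_variant_intervals=4,
            no_variant_interval_length_bp=45_000, n_offspring=2,
            dnm_spike_per_offspring=15, pzm_spike_per_offspring=8)


def tiny_config(seed=3, **kw):
    return SimConfig(**{**TINY, **kw, "seed": seed})


class TestSnpPlacement:
    def test_zero_weight_window_gets_no_snps(self):
        cfg = tiny_config()
        rng = np.random.default_rng(0)
        # a no-variant interval covering one whole window zeroes its weight
        intervals = [(100_000, 200_000)]
        with pytest.warns(UserWarning, match="fully covered"):
            pos, counts = simulate_snp_positions(cfg, rng, intervals)
        assert counts[1] == 0
        assert not np.any((pos >= 100_000) & (pos < 200_000))

    def test_no_snp_inside_no_variant_intervals(self):
        cfg = tiny_config()
        rng = np.random.default_rng(1)
        intervals = place_no_variant_intervals(cfg, rng)
        pos, _ = simulate_snp_positions(cfg, rng, intervals)
        for s, e in intervals:
            assert not np.any((pos >= s) & (pos < e))

    def test_positions_unique_and_in_range(self):
        cfg = tiny_config()
        rng = np.random.default_rng(2)
        pos, _ = simulate_snp_positions(cfg, rng, [])
        assert len(np.unique(pos)) == len(pos)
        assert pos.min() >= 0 and pos.max() < cfg.genome_length_bp

    def test_per_window_counts_are_poisson(self):
        """Dispersion test across seeds: counts ~ Poisson at the 1% level."""
        cfg = SimConfig(genome_length_bp=1_000_000, n_no_variant_intervals=1,
                        no_variant_interval_length_bp=1_000, heterozygosity=0.005,
                        seed=0)
        rejections = 0
        n_seeds = 120
        for s in range(n_seeds):
            rng = np.random.default_rng(10_000 + s)
            _, counts = simulate_snp_positions(cfg, rng, [])
            counts = np.asarray(counts, float)
            d = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
            p = stats.chi2.sf(d, len(counts) - 1)
            if p < 0.01 or p > 0.99:
                rejections += 1
        assert rejections <= int(0.02 * n_seeds) + 4


class TestSimulateParent:
    def test_zero_heterozygosity_identical_haplotypes(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 4, size=10_000, dtype=np.uint8)
        h0, h1 = simulate_parent(ref, np.empty(0, dtype=np.int64), rng)
        assert np.array_equal(h0, ref) and np.array_equal(h1, ref)

    def test_observed_heterozygosity_matches_target(self):
        rng = np.random.default_rng(1)
        L = 200_000
        ref = rng.integers(0, 4, size=L, dtype=np.uint8)
        target = 0.03
        pos = np.sort(rng.choice(L, size=int(target * L), replace=False))
        h0, h1 = simulate_parent(ref, pos, rng)
        observed = np.mean(h0 != h1)
        assert observed == pytest.approx(target, rel=0.02)

    def test_truth_positions_exactly_match_sequence_differences(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 4, size=50_000, dtype=np.uint8)
        pos = np.sort(rng.choice(50_000, size=1000, replace=False))
        h0, h1 = simulate_parent(ref, pos, rng)
        assert np.array_equal(np.flatnonzero(h0 != h1), pos)
        # exactly one haplotype deviates from the reference at each site
        assert np.all((h0[pos] == ref[pos]) ^ (h1[pos] == ref[pos]))


class TestContigize:
    def test_mislabel_zero_matches_truth(self):
        sim = simulate_pedigree(tiny_config(nonbubble_mislabel_fraction=0.0))
        for c in sim.contigs:
            truth = sim.truth.true_zygosity[c.contig_id]
            if truth == "het":
                assert c.assembler_class != NON_BUBBLE
            else:
                assert c.assembler_class == NON_BUBBLE

    def test_mislabel_fraction_recovered(self):
        sim = simulate_pedigree(tiny_config(seed=9))
        het_pairs = {c.contig_id[:-2] for c in sim.contigs
                     if sim.truth.true_zygosity[c.contig_id] == "het"}
        mislabeled = {c.contig_id[:-2] for c in sim.contigs
                      if sim.truth.true_zygosity[c.contig_id] == "het"
                      and c.assembler_class == NON_BUBBLE}
        frac = len(mislabeled) / len(het_pairs)
        assert frac == pytest.approx(0.5, abs=0.08)

    def test_no_variant_segments_emit_single_contigs(self):
        sim = simulate_pedigree(tiny_config())
        for cid, meta in sim.meta.items():
            if meta.segment.no_variant:
                assert meta.hap is None
                assert sim.truth.true_zygosity[cid] == "hom"

    def test_segments_tile_genome(self):
        cfg = tiny_config()
        rng = np.random.default_rng(5)
        intervals = place_no_variant_intervals(cfg, rng)
        segs = make_segments(cfg, intervals, rng)
        assert segs[0].start == 0 and segs[-1].end == cfg.genome_length_bp
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        assert min(s.length for s in segs) >= cfg.min_segment_length_bp


class TestTransmission:
    def test_same_seed_identical_transmission(self):
        a = simulate_pedigree(tiny_config(seed=4))
        b = simulate_pedigree(tiny_config(seed=4))
        assert a.truth.transmitted == b.truth.transmitted

    def test_haplotype_frequencies_near_half(self):
        sim = simulate_pedigree(tiny_config(seed=5, n_offspring=6))
        draws = np.array(list(sim.truth.transmitted.values()))
        assert draws.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(draws.size))

    def test_shared_segments_flagged_in_truth(self):
        sim = simulate_pedigree(tiny_config(seed=6))
        shared = [s for s in sim.truth.segments if s.shared]
        assert shared
        mh0 = sim.haplotypes["maternal"][0]
        fh0 = sim.haplotypes["paternal"][0]
        for s in shared[:10]:
            assert np.array_equal(mh0[s.start:s.end], fh0[s.start:s.end])


class TestDepthModel:
    def test_cross_mapping_zero_gives_zero_depth_on_non_inherited(self):
        sim = simulate_pedigree(tiny_config(seed=7, cross_mapping_rate=0.0))
        off = "o1"
        checked = 0
        for cid, meta in sim.meta.items():
            if meta.hap is None or meta.segment.shared:
                continue
            if sim.true_inheritance_state(off, cid) == INHERITED:
                continue
            assert sim.combined_tracks[off][cid].mean() == 0.0
            checked += 1
        assert checked > 20

    def test_generated_depth_mean_within_two_percent_at_scale(self):
        sim = simulate_pedigree(tiny_config(seed=8, depth_contig_cv=0.0))
        means, weights = [], []
        for cid, meta in sim.meta.items():
            if meta.hap is None:
                t = sim.self_tracks["mother"].get(cid)
                if t is not None:
                    means.append(t.mean())
                    weights.append(t.length)
        overall = np.average(means, weights=weights)
        assert overall == pytest.approx(sim.config.depth_mean, rel=0.02)

    def test_full_determinism_same_seed(self):
        a = simulate_pedigree(tiny_config(seed=12))
        b = simulate_pedigree(tiny_config(seed=12))
        assert [c.contig_id for c in a.contigs] == [c.contig_id for c in b.contigs]
        for cid in list(a.combined_tracks["o1"])[:50]:
            assert np.array_equal(a.combined_tracks["o1"][cid].values,
                                  b.combined_tracks["o1"][cid].values)
        assert a.cross_paf == b.cross_paf


@pytest.fixture(scope="module")
def spiked():
    from haplodnm.simulate import run_pipeline
    sim = simulate_pedigree(tiny_config(seed=13, n_offspring=3))
    *_, callables = run_pipeline(sim)
    sim.spike_mutations(callables)
    obs = sim.make_observations()
    return sim, callables, obs


class TestSpiking:
    def test_spike_counts_exact(self, spiked):
        sim, _, _ = spiked
        for off in sim.config.offspring_ids:
            n = sum(1 for m in sim.truth.dnms if m.offspring_id == off)
            assert n == sim.config.dnm_spike_per_offspring

    def test_spikes_inside_callable(self, spiked):
        sim, callables, _ = spiked
        for m in sim.truth.dnms:
            assert callables[m.offspring_id].contains(m.contig_id, m.pos)

    def test_shared_spikes_identical_across_carriers(self, spiked):
        sim, _, _ = spiked
        groups = {}
        for m in sim.truth.dnms:
            if m.shared_group_id:
                groups.setdefault(m.shared_group_id, []).append(m)
        assert groups
        for recs in groups.values():
            assert len(recs) >= 2
            assert len({(m.contig_id, m.pos, m.alt_base) for m in recs}) == 1
            assert len({m.offspring_id for m in recs}) == len(recs)

    def test_mendelian_spikes_lie_on_inherited_contigs(self, spiked):
        sim, _, _ = spiked
        for m in sim.truth.dnms:
            assert sim.true_inheritance_state(m.offspring_id, m.contig_id) == INHERITED

    def test_hom_dnm_sites_alt_in_offspring_absent_in_parents(self, spiked):
        sim, _, obs = spiked
        from haplodnm.core_io import CALLER_PILEUP
        sites = {(m.offspring_id, m.contig_id, m.pos): m for m in sim.truth.dnms}
        seen = 0
        for off, callers in obs.items():
            for o in callers[CALLER_PILEUP]:
                m = sites.get((off, o.contig_id, o.pos))
                if m is None:
                    continue
                oc = o.samples[off]
                if oc.genotype == (1, 1):
                    seen += 1
                    assert oc.allele_depths[1] == oc.total_depth
                    for parent in ("mother", "father"):
                        pc = o.samples[parent]
                        assert pc.allele_depths is None or pc.allele_depths[1] == 0
        assert seen > 20

    def test_excessive_spike_request_is_error(self):
        from haplodnm.simulate import run_pipeline
        sim = simulate_pedigree(tiny_config(seed=14, n_offspring=1,
                                            dnm_spike_per_offspring=10**7))
        *_, callables = run_pipeline(sim)
        with pytest.raises(ValueError):
            sim.spike_mutations(callables)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(heterozygosity=1.5)
    with pytest.raises(ValueError):
        SimConfig(genome_length_bp=100_000)  # defaults' no-variant intervals exceed genome
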