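"""Synthetic diploid pedigree generator and benchmark harnesses.

The generator stands in for the assembler and aligner stages of a real
pedigree-sequencing experiment.  It simulates two highly heterozygous
parents (~3% genome-wide heterozygosity placed by a window-based
inhomogeneous Poisson process, with predefined homozygous "no-variant"
intervals), contigizes each parent's diploid genome into bubble pairs and
single homozygous contigs (with a configurable fraction of bubble pairs
mislabeled as assembler non-bubble output, emulating failed phasing),
transmits one haplotype per segment per parent to each offspring, spikes
germline and postzygotic mutations with full truth records, and emits the
observation-level artifacts the detection pipeline consumes: per-base depth
tracks (negative-binomial bin depths with sparse cross-mapping bleed
between similar alleles), self- and cross-parent alignment PAFs, and
two-caller trio variant observations with decoy artifacts that exercise
every filter.

Everything downstream of read alignment is preserved quantitatively;
read-level simulation is the documented extension point this generator
deliberately replaces with parametric models.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .callable_genome import CallableSet, cross_parent_homologs, find_similar_allele_pairs
from .contig_classify import CAT_BUBBLE_LIKE, CAT_TRUE_NON_BUBBLE, ZygosityCall
from .core_io import (
    BUBBLE_PRIMARY,
    BUBBLE_SECONDARY,
    CALLER_HAPLOTYPE,
    CALLER_PILEUP,
    NON_BUBBLE,
    ContigRecord,
    ConversionMask,
    DepthTrack,
    PafRecord,
    SampleCall,
    VariantObservation,
)
from .inheritance import INHERITED, NOT_INHERITED, UNRESOLVED
from .rates import false_negative_rate, mutation_rate
from .variant_filter import DnmRecord, group_shared_dnms, pzm_filter
from . import pipeline

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MOTHER = "mother"
FATHER = "father"


@dataclass
class SimConfig:
    """Study conditions of the synthetic pedigree.

    Defaults mirror the real experiment this generator emulates: ~3%
    genome-wide heterozygosity, ~80x sequencing depth per individual,
    half of the heterozygous bubble pairs mislabeled by the assembler,
    lognormal contig lengths with N50 ~ 7 kb, and enough homozygous
    sequence and cross-parent allele sharing (the parents are inbred) that
    the per-offspring callable fraction of the diploid genome lands in the
    observed 34-51% band.
    """

    genome_length_bp: int = 5_000_000
    window_size_bp: int = 100_000
    window_weight_gamma_shape: Optional[float] = None  # None = uniform weights
    heterozygosity: float = 0.03
    n_no_variant_intervals: int = 28
    no_variant_interval_length_bp: int = 80_000
    n_offspring: int = 3
    depth_mean: float = 80.0
    depth_nb_dispersion: float = 10.0
    depth_contig_cv: float = 0.10
    cross_mapping_rate: float = 0.05
    shared_ancestry_fraction: float = 0.45
    dnm_spike_per_offspring: int = 50
    shared_dnm_fraction: float = 0.20
    pzm_spike_per_offspring: int = 20
    pzm_vaf_beta: tuple[float, float] = (2.0, 8.0)
    nonbubble_mislabel_fraction: float = 0.50
    segment_length_median_bp: int = 5_500
    segment_length_sigma: float = 0.50
    min_segment_length_bp: int = 500
    qual_mean: float = 400.0
    qual_sd: float = 60.0
    low_qual_fraction: float = 0.03
    caller_miss_rate: float = 0.01
    indel_decoys_per_offspring: int = 10
    conversion_decoys_per_offspring: int = 10
    het_decoys_per_offspring: int = 10
    bin_size_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "heterozygosity", "cross_mapping_rate", "shared_ancestry_fraction",
            "shared_dnm_fraction", "nonbubble_mislabel_fraction",
            "low_qual_fraction", "caller_miss_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.genome_length_bp <= 0 or self.depth_mean <= 0:
            raise ValueError("genome_length_bp and depth_mean must be positive")
        covered = self.n_no_variant_intervals * self.no_variant_interval_length_bp
        if covered >= self.genome_length_bp:
            raise ValueError("no-variant intervals cover the whole genome")
        # classification needs a bimodal contig-depth histogram: at the
        # default thresholds the haploid and diploid peaks must be separable
        if self.depth_contig_cv > 0.25:
            warnings.warn(
                "depth_contig_cv > 0.25 blurs the haploid/diploid depth "
                "bimodality that contig classification relies on",
                stacklevel=2,
            )

    @property
    def offspring_ids(self) -> list[str]:
        return [f"o{i + 1}" for i in range(self.n_offspring)]


@dataclass
class Segment:
    index: int
    start: int
    end: int
    no_variant: bool
    shared: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpikedMutation:
    offspring_id: str
    contig_id: str
    pos: int
    ref_base: str
    alt_base: str
    origin: str
    shared_group_id: Optional[str] = None
    true_vaf: Optional[float] = None  # set for PZMs only


@dataclass
class TruthSet:
    snp_positions: dict[str, np.ndarray] = field(default_factory=dict)
    no_variant_intervals: list[tuple[int, int]] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    true_zygosity: dict[str, str] = field(default_factory=dict)  # contig -> het|hom
    transmitted: dict[tuple[str, str, int], int] = field(default_factory=dict)
    true_inherited: dict[str, set[str]] = field(default_factory=dict)
    dnms: list[SpikedMutation] = field(default_factory=list)
    pzms: list[SpikedMutation] = field(default_factory=list)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def place_no_variant_intervals(config: SimConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Randomly place non-overlapping no-variant intervals on the genome."""
    n = config.n_no_variant_intervals
    ilen = config.no_variant_interval_length_bp
    slack = config.genome_length_bp - n * ilen
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    out = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        out.append((pos, pos + ilen))
        pos += ilen
    return out


def simulate_snp_positions(
    config: SimConfig,
    rng: np.random.Generator,
    no_variant_intervals: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Window-based inhomogeneous Poisson SNP placement.

    The target total (heterozygosity x genome length) is distributed over
    windows in proportion to their weights via independent Poisson draws;
    positions fall uniformly within each window, excluding no-variant
    intervals.  Returns (sorted unique positions, per-window counts).
    """
    L = config.genome_length_bp
    w = config.window_size_bp
    n_win = math.ceil(L / w)
    if config.window_weight_gamma_shape is None:
        weights = np.ones(n_win)
    else:
        k = config.window_weight_gamma_shape
        weights = rng.gamma(k, 1.0 / k, size=n_win)
    # allowed sub-intervals per window
    allowed: list[list[tuple[int, int]]] = []
    for i in range(n_win):
        ws, we = i * w, min((i + 1) * w, L)
        ivs = [(ws, we)]
        for ns, ne in no_variant_intervals:
            nxt = []
            for a, b in ivs:
                if ne <= a or ns >= b:
                    nxt.append((a, b))
                else:
                    if a < ns:
                        nxt.append((a, ns))
                    if ne < b:
                        nxt.append((ne, b))
            ivs = nxt
        allowed.append(ivs)
        if not ivs and weights[i] > 0:
            warnings.warn(
                f"window {i} is fully covered by no-variant intervals; "
                "its weight is dropped",
                stacklevel=2,
            )
            weights[i] = 0.0
    if not np.any(weights > 0):
        raise ValueError("all window weights are zero")
    target = round(config.heterozygosity * L)
    lam = target * weights / weights.sum()
    counts = rng.poisson(lam)
    positions: list[np.ndarray] = []
    for i in range(n_win):
        c = int(counts[i])
        if c == 0 or not allowed[i]:
            counts[i] = 0 if not allowed[i] else counts[i]
            continue
        lens = np.array([b - a for a, b in allowed[i]])
        starts = np.array([a for a, _ in allowed[i]])
        offsets = np.concatenate(([0], np.cumsum(lens)))
        total = int(lens.sum())
        draws = rng.integers(0, total, size=c)
        for _ in range(8):  # redraw duplicates
            draws = np.unique(draws)
            if draws.size >= c or draws.size >= total:
                break
            extra = rng.integers(0, total, size=c - draws.size)
            draws = np.concatenate((draws, extra))
        idx = np.searchsorted(offsets, draws, side="right") - 1
        positions.append(starts[idx] + (draws - offsets[idx]))
        counts[i] = draws.size
    pos = np.sort(np.concatenate(positions)) if positions else np.empty(0, dtype=np.int64)
    return pos.astype(np.int64), counts


def simulate_parent(
    reference: np.ndarray,
    snp_positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Introduce heterozygous SNPs: each site mutates one random haplotype."""
    h0 = reference.copy()
    h1 = reference.copy()
    if snp_positions.size:
        which = rng.integers(0, 2, size=snp_positions.size)
        shift = rng.integers(1, 4, size=snp_positions.size).astype(np.uint8)
        alts = (reference[snp_positions] + shift) % 4
        h0[snp_positions[which == 0]] = alts[which == 0]
        h1[snp_positions[which == 1]] = alts[which == 1]
    return h0, h1


def make_segments(config: SimConfig, no_variant_intervals: Sequence[tuple[int, int]],
                  rng: np.random.Generator) -> list[Segment]:
    """Partition the genome into contig-sized segments.

    Segment boundaries respect no-variant interval boundaries so that each
    segment is entirely heterozygous-eligible or entirely homozygous;
    lengths are lognormal around the configured median.
    """
    bounds = [0]
    for s, e in sorted(no_variant_intervals):
        bounds.extend((s, e))
    bounds.append(config.genome_length_bp)
    regions = []
    no_var = False
    for a, b in zip(bounds, bounds[1:]):
        if b > a:
            regions.append((a, b, no_var))
        no_var = not no_var
    segments: list[Segment] = []
    mu = math.log(config.segment_length_median_bp)
    sigma = config.segment_length_sigma
    idx = 0
    for a, b, nv in regions:
        pos = a
        while pos < b:
            length = int(rng.lognormal(mu, sigma))
            length = max(length, config.min_segment_length_bp)
            end = min(pos + length, b)
            if b - end < config.min_segment_length_bp:
                end = b
            segments.append(Segment(idx, pos, end, no_variant=nv))
            idx += 1
            pos = end
    return segments


@dataclass
class _ContigMeta:
    parent: str          # maternal | paternal
    segment: Segment
    hap: Optional[int]   # 0/1 for bubble members, None for homozygous contigs
    mislabeled: bool = False


class PedigreeSimulation:
    """A fully generated pedigree with truth records and pipeline inputs."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.truth = TruthSet()
        self.contigs: list[ContigRecord] = []
        self.meta: dict[str, _ContigMeta] = {}
        self.self_paf: dict[str, list[PafRecord]] = {}
        self.cross_paf: list[PafRecord] = []
        self.self_tracks: dict[str, dict[str, DepthTrack]] = {}
        self.combined_tracks: dict[str, dict[str, DepthTrack]] = {}
        self.reference: Optional[np.ndarray] = None
        self.haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._streams: dict[str, np.random.Generator] = {}

    # -- deterministic per-purpose random streams -------------------------
    def _rng(self, purpose: str) -> np.random.Generator:
        if purpose not in self._streams:
            tag = zlib.crc32(purpose.encode("ascii"))
            ss = np.random.SeedSequence([self.config.seed, tag])
            self._streams[purpose] = np.random.default_rng(ss)
        return self._streams[purpose]

    # -- generation steps -------------------------------------------------
    def generate(self) -> "PedigreeSimulation":
        cfg = self.config
        rng = self._rng("genome")
        self.reference = rng.integers(0, 4, size=cfg.genome_length_bp, dtype=np.uint8)
        self.truth.no_variant_intervals = place_no_variant_intervals(cfg, rng)
        for parent in ("maternal", "paternal"):
            pos, _ = simulate_snp_positions(cfg, self._rng(f"snps_{parent}"), self.truth.no_variant_intervals)
            self.truth.snp_positions[parent] = pos
            self.haplotypes[parent] = simulate_parent(self.reference, pos, self._rng(f"mut_{parent}"))
        self.truth.segments = make_segments(cfg, self.truth.no_variant_intervals, self._rng("segments"))
        self._apply_shared_ancestry()
        self._contigize()
        self._transmit()
        self._make_alignments()
        self._make_depths()
        return self

    def _segment_is_het(self, parent: str, seg: Segment) -> bool:
        h0, h1 = self.haplotypes[parent]
        return bool(np.any(h0[seg.start:seg.end] != h1[seg.start:seg.end]))

    def _apply_shared_ancestry(self) -> None:
        """Copy the mother's first haplotype into the father at shared segments."""
        rng = self._rng("shared")
        candidates = [
            s for s in self.truth.segments
            if not s.no_variant
            and self._segment_is_het("maternal", s)
            and self._segment_is_het("paternal", s)
        ]
        n_shared = int(round(self.config.shared_ancestry_fraction * len(candidates)))
        chosen = rng.choice(len(candidates), size=n_shared, replace=False) if n_shared else []
        mh0 = self.haplotypes["maternal"][0]
        fh0 = self.haplotypes["paternal"][0]
        for i in chosen:
            seg = candidates[i]
            fh0[seg.start:seg.end] = mh0[seg.start:seg.end]
            seg.shared = True

    def _contigize(self) -> None:
        cfg = self.config
        rng = self._rng("contigize")
        prefix = {"maternal": "m", "paternal": "f"}
        for parent in ("maternal", "paternal"):
            h0, h1 = self.haplotypes[parent]
            for seg in self.truth.segments:
                tag = f"{prefix[parent]}s{seg.index}"
                if seg.no_variant or not self._segment_is_het(parent, seg):
                    cid = f"{tag}n"
                    self.contigs.append(ContigRecord(
                        cid, parent, NON_BUBBLE, seg.length,
                        sequence=_codes_to_str(h0[seg.start:seg.end]),
                    ))
                    self.meta[cid] = _ContigMeta(parent, seg, None)
                    self.truth.true_zygosity[cid] = "hom"
                    continue
                mislabel = rng.random() < cfg.nonbubble_mislabel_fraction
                ids = (f"{tag}h0", f"{tag}h1")
                for hap, cid in enumerate(ids):
                    seq = _codes_to_str((h0 if hap == 0 else h1)[seg.start:seg.end])
                    if mislabel:
                        rec = ContigRecord(cid, parent, NON_BUBBLE, seg.length, sequence=seq)
                    else:
                        cls = BUBBLE_PRIMARY if hap == 0 else BUBBLE_SECONDARY
                        rec = ContigRecord(cid, parent, cls, seg.length,
                                           partner_id=ids[1 - hap], sequence=seq)
                    self.contigs.append(rec)
                    self.meta[cid] = _ContigMeta(parent, seg, hap, mislabeled=mislabel)
                    self.truth.true_zygosity[cid] = "het"

    def _transmit(self) -> None:
        rng = self._rng("transmit")
        for off in self.config.offspring_ids:
            inherited: set[str] = set()
            for parent in ("maternal", "paternal"):
                for seg in self.truth.segments:
                    self.truth.transmitted[(off, parent, seg.index)] = int(rng.integers(0, 2))
            for cid, meta in self.meta.items():
                if self._true_dose(off, cid) > 0:
                    inherited.add(cid)
            self.truth.true_inherited[off] = inherited

    def _true_dose(self, individual: str, cid: str) -> float:
        """Haplotype dose of an individual's reads on a combined-reference contig."""
        meta = self.meta[cid]
        seg = meta.segment
        if meta.hap is None:  # homozygous contig: diploid dose for everyone
            return 2.0
        if individual in (MOTHER, FATHER):
            own = (individual == MOTHER) == (meta.parent == "maternal")
            if seg.shared and meta.hap == 0:
                return 0.5  # reads from the shared allele split across both copies
            return 1.0 if own else 0.0
        hm = self.truth.transmitted[(individual, meta.parent, seg.index)]
        if seg.shared and meta.hap == 0:
            other_parent = "paternal" if meta.parent == "maternal" else "maternal"
            ho = self.truth.transmitted[(individual, other_parent, seg.index)]
            return 0.5 * (hm == 0) + 0.5 * (ho == 0)
        return 1.0 if hm == meta.hap else 0.0

    def true_inheritance_state(self, offspring_id: str, cid: str) -> str:
        """Truth label for the inheritance of a contig's haplotype."""
        meta = self.meta[cid]
        if meta.hap is None:
            return INHERITED
        h = self.truth.transmitted[(offspring_id, meta.parent, meta.segment.index)]
        return INHERITED if h == meta.hap else NOT_INHERITED

    # -- alignments -------------------------------------------------------
    def _identity(self, a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
        n = min(a.size, b.size)
        return int(np.sum(a[:n] == b[:n])), n

    def _pair_records(self, ca: str, cb: str, seq_a: np.ndarray, seq_b: np.ndarray) -> list[PafRecord]:
        matches, block = self._identity(seq_a, seq_b)
        la, lb = seq_a.size, seq_b.size
        return [
            PafRecord(ca, la, 0, min(la, block), "+", cb, lb, 0, min(lb, block), matches, block, 60),
            PafRecord(cb, lb, 0, min(lb, block), "+", ca, la, 0, min(la, block), matches, block, 60),
        ]

    def _make_alignments(self) -> None:
        rng = self._rng("alignments")
        seqs: dict[str, np.ndarray] = {}
        for parent in ("maternal", "paternal"):
            h0, h1 = self.haplotypes[parent]
            for cid, meta in self.meta.items():
                if meta.parent != parent:
                    continue
                hap = self.haplotypes[parent][meta.hap or 0]
                seqs[cid] = hap[meta.segment.start:meta.segment.end]
        # self alignment per parent: allelic pairs + partial-coverage decoys
        for parent in ("maternal", "paternal"):
            records: list[PafRecord] = []
            own = [cid for cid, m in self.meta.items() if m.parent == parent]
            for cid in own:
                meta = self.meta[cid]
                if meta.hap == 0:
                    partner = cid[:-2] + "h1"
                    records.extend(self._pair_records(cid, partner, seqs[cid], seqs[partner]))
            n_decoys = max(1, len(own) // 10)
            for _ in range(n_decoys):
                a, b = rng.choice(own, size=2, replace=False)
                la, lb = seqs[a].size, seqs[b].size
                span = max(60, int(0.3 * min(la, lb)))
                matches = int(span * rng.uniform(0.85, 0.95))
                records.append(PafRecord(a, la, 0, span, "+", b, lb, 0, span, matches, span, 60))
            self.self_paf[parent] = records
        # cross-parent alignment: allelic combinations per segment
        for seg in self.truth.segments:
            m_ids = [c for c, m in self.meta.items()
                     if m.parent == "maternal" and m.segment.index == seg.index]
            f_ids = [c for c, m in self.meta.items()
                     if m.parent == "paternal" and m.segment.index == seg.index]
            for a in m_ids:
                for b in f_ids:
                    self.cross_paf.extend(self._pair_records(a, b, seqs[a], seqs[b]))

    # -- depth ------------------------------------------------------------
    def _nb(self, rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size)
        r = self.config.depth_nb_dispersion
        return rng.negative_binomial(r, r / (r + mean), size=size).astype(np.float64)

    def _gen_track(self, rng: np.random.Generator, cid: str, individual: str,
                   length: int, dose: float, bleed: bool) -> DepthTrack:
        cfg = self.config
        bin_ = cfg.bin_size_bp
        n_bins = math.ceil(length / bin_)
        mean = dose * cfg.depth_mean / 2.0
        if cfg.depth_contig_cv > 0 and mean > 0:
            k = 1.0 / cfg.depth_contig_cv**2
            mean *= rng.gamma(k, 1.0 / k)
        vals = self._nb(rng, mean, n_bins)
        if bleed and dose == 0 and cfg.cross_mapping_rate > 0:
            mask = rng.random(n_bins) < cfg.cross_mapping_rate
            n_hit = int(mask.sum())
            if n_hit:
                vals[mask] += self._nb(rng, cfg.depth_mean / 2.0, n_hit)
        starts = np.arange(n_bins, dtype=np.int64) * bin_
        ends = np.minimum(starts + bin_, length)
        return DepthTrack(cid, individual, starts, ends, vals)

    def _make_depths(self) -> None:
        cfg = self.config
        rng = self._rng("depth")
        individuals = [MOTHER, FATHER] + cfg.offspring_ids
        for parent, pid in (("maternal", MOTHER), ("paternal", FATHER)):
            tracks: dict[str, DepthTrack] = {}
            for cid, meta in self.meta.items():
                if meta.parent != parent:
                    continue
                dose = 2.0 if meta.hap is None else 1.0
                tracks[cid] = self._gen_track(rng, cid, pid, meta.segment.length, dose, bleed=False)
            self.self_tracks[pid] = tracks
        for ind in individuals:
            tracks = {}
            for cid, meta in self.meta.items():
                dose = self._true_dose(ind, cid)
                bleed = meta.hap is not None
                tracks[cid] = self._gen_track(rng, cid, ind, meta.segment.length, dose, bleed)
            self.combined_tracks[ind] = tracks

    # -- mutation spiking and variant observations ------------------------
    def _sample_callable_positions(self, rng: np.random.Generator,
                                   cset: CallableSet, n: int,
                                   phased_only: bool = False) -> list[tuple[str, int]]:
        pools = [dict(cset.phased_intervals)]
        if not phased_only:
            pools.append(dict(cset.unphased_intervals))
        entries: list[tuple[str, int, int]] = []
        for pool in pools:
            for cid, ivs in pool.items():
                for s, e in ivs:
                    entries.append((cid, s, e))
        if not entries:
            raise ValueError("no eligible positions for mutation spiking")
        lens = np.array([e - s for _, s, e in entries], dtype=float)
        total = int(lens.sum())
        if n > total:
            raise ValueError("requested spike count exceeds eligible positions")
        out: set[tuple[str, int]] = set()
        probs = lens / lens.sum()
        while len(out) < n:
            i = rng.choice(len(entries), p=probs)
            cid, s, e = entries[i]
            out.add((cid, int(rng.integers(s, e))))
        return sorted(out)

    def spike_mutations(self, callable_sets: Mapping[str, CallableSet]) -> None:
        """Place DNMs (some shared between siblings) and PZMs with truth."""
        cfg = self.config
        rng = self._rng("spike")
        offspring = cfg.offspring_ids
        for o in offspring:
            cs = callable_sets[o]
            eligible = sum(e - s for ivs in cs.phased_intervals.values() for s, e in ivs)
            eligible += sum(e - s for ivs in cs.unphased_intervals.values() for s, e in ivs)
            if cfg.dnm_spike_per_offspring + cfg.pzm_spike_per_offspring > eligible:
                raise ValueError(
                    f"{o}: requested spike count exceeds eligible callable positions")
        remaining = {o: cfg.dnm_spike_per_offspring for o in offspring}
        used: set[tuple[str, str, int]] = set()
        group_no = 0
        # early-germline shared DNMs, placed into k >= 2 siblings
        if len(offspring) >= 2 and cfg.shared_dnm_fraction > 0:
            target_shared = int(round(cfg.shared_dnm_fraction * cfg.dnm_spike_per_offspring
                                      * len(offspring)))
            placed = 0
            attempts = 0
            while placed < target_shared and attempts < 50 * target_shared:
                attempts += 1
                k = 2 if len(offspring) == 2 or rng.random() < 0.8 else 3
                group = list(rng.choice(offspring, size=k, replace=False))
                if any(remaining[o] <= 0 for o in group):
                    continue
                cid, pos = self._sample_callable_positions(rng, callable_sets[group[0]], 1)[0]
                if self.meta[cid].hap is None:
                    continue
                if not all(callable_sets[o].contains(cid, pos) for o in group):
                    continue
                if any(self.true_inheritance_state(o, cid) != INHERITED for o in group):
                    continue
                if any((o, cid, pos) in used for o in group):
                    continue
                group_no += 1
                ref, alt = self._draw_alt(rng, cid, pos)
                for o in group:
                    self.truth.dnms.append(SpikedMutation(
                        o, cid, pos, ref, alt, self.meta[cid].parent,
                        shared_group_id=f"truth_ssg{group_no}",
                    ))
                    used.add((o, cid, pos))
                    remaining[o] -= 1
                    placed += 1
        for o in offspring:
            n = remaining[o]
            tries = 0
            while n > 0 and tries < 50 * cfg.dnm_spike_per_offspring:
                tries += 1
                cid, pos = self._sample_callable_positions(rng, callable_sets[o], 1)[0]
                if (o, cid, pos) in used or self.meta[cid].hap is None:
                    continue
                ref, alt = self._draw_alt(rng, cid, pos)
                self.truth.dnms.append(SpikedMutation(o, cid, pos, ref, alt, self.meta[cid].parent))
                used.add((o, cid, pos))
                n -= 1
        a, b = cfg.pzm_vaf_beta
        for o in offspring:
            sites = self._sample_callable_positions(rng, callable_sets[o],
                                                    cfg.pzm_spike_per_offspring, phased_only=True)
            for cid, pos in sites:
                if (o, cid, pos) in used or self.meta[cid].hap is None:
                    continue
                ref, alt = self._draw_alt(rng, cid, pos)
                self.truth.pzms.append(SpikedMutation(
                    o, cid, pos, ref, alt, self.meta[cid].parent,
                    true_vaf=float(rng.beta(a, b)),
                ))
                used.add((o, cid, pos))

    def _draw_alt(self, rng: np.random.Generator, cid: str, pos: int) -> tuple[str, str]:
        if not hasattr(self, "_seq_cache"):
            self._seq_cache = {c.contig_id: c.sequence for c in self.contigs}
        ref = self._seq_cache[cid][pos]
        alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        return ref, alt

    def _qual(self, rng: np.random.Generator) -> float:
        if rng.random() < self.config.low_qual_fraction:
            return float(rng.uniform(100, 219))
        return float(np.clip(rng.normal(self.config.qual_mean, self.config.qual_sd), 230, 1500))

    def _dp(self, individual: str, cid: str, pos: int) -> int:
        return int(round(self.combined_tracks[individual][cid].value_at(pos)))

    def _site_samples(self, rng: np.random.Generator, offspring_id: str, cid: str, pos: int,
                      gt: tuple[int, int], alt_frac: float = 1.0) -> dict[str, SampleCall]:
        """FORMAT fields for (mother, father, offspring) at a candidate site."""
        samples: dict[str, SampleCall] = {}
        for ind in (MOTHER, FATHER):
            dp = self._dp(ind, cid, pos)
            samples[ind] = SampleCall((0, 0) if dp else None, dp, (dp, 0))
        dp = self._dp(offspring_id, cid, pos)
        if gt == (1, 1):
            ad_alt = dp
        else:
            ad_alt = int(rng.binomial(dp, min(1.0, alt_frac))) if dp else 0
        samples[offspring_id] = SampleCall(gt, dp, (dp - ad_alt, ad_alt))
        return samples

    def make_observations(self) -> dict[str, dict[str, list[VariantObservation]]]:
        """Two-caller trio observations per offspring, decoys included.

        The haplotype-aware caller covers contigs at shared-ancestry
        segments and homozygous contigs (where cross-parent similarity is
        high); the pileup caller covers everything.  Decoy artifacts: an
        INDEL near a DNM-like site, DNM-like sites at gene-conversion
        positions, and DNM-like sites that another sibling carries as
        heterozygous.
        """
        cfg = self.config
        rng = self._rng("observations")
        out: dict[str, dict[str, list[VariantObservation]]] = {
            o: {CALLER_PILEUP: [], CALLER_HAPLOTYPE: []} for o in cfg.offspring_ids
        }
        self.conversion_sites: list[tuple[str, int]] = []
        self.het_decoy_sites: dict[tuple[str, int], str] = {}

        def emit(off: str, cid: str, pos: int, ref: str, alt: str,
                 gt: tuple[int, int], alt_frac: float = 1.0,
                 qual: Optional[float] = None) -> None:
            if rng.random() < cfg.caller_miss_rate:
                return
            q = self._qual(rng) if qual is None else qual
            obs_samples = self._site_samples(rng, off, cid, pos, gt, alt_frac)
            meta = self.meta[cid]
            high_sim = meta.hap is None or meta.segment.shared
            for caller in (CALLER_PILEUP, CALLER_HAPLOTYPE):
                if caller == CALLER_HAPLOTYPE and not high_sim:
                    continue
                out[off][caller].append(VariantObservation(
                    cid, pos, ref, (alt,), q, caller, dict(obs_samples)))

        for m in self.truth.dnms:
            emit(m.offspring_id, m.contig_id, m.pos, m.ref_base, m.alt_base, (1, 1))
        for m in self.truth.pzms:
            emit(m.offspring_id, m.contig_id, m.pos, m.ref_base, m.alt_base,
                 (0, 1), alt_frac=min(1.0, 2 * (m.true_vaf or 0.0)))

        # decoys
        phased_contigs = [cid for cid, m in self.meta.items()
                          if m.hap is not None and not m.segment.shared]
        for off in cfg.offspring_ids:
            inherited = [c for c in phased_contigs
                         if self.true_inheritance_state(off, c) == INHERITED]
            for _ in range(cfg.indel_decoys_per_offspring):
                cid = inherited[int(rng.integers(len(inherited)))]
                length = self.meta[cid].segment.length
                pos = int(rng.integers(150, max(151, length - 150)))
                ref, alt = self._draw_alt(rng, cid, pos)
                d = int(rng.integers(1, 21))
                iref, _ = self._draw_alt(rng, cid, pos + d)
                out[off][CALLER_PILEUP].append(VariantObservation(
                    cid, pos + d, iref, (iref + "T",), 300.0, CALLER_PILEUP,
                    self._site_samples(rng, off, cid, pos + d, (0, 1), 0.5)))
                emit(off, cid, pos, ref, alt, (1, 1))
            for _ in range(cfg.conversion_decoys_per_offspring):
                cid = inherited[int(rng.integers(len(inherited)))]
                length = self.meta[cid].segment.length
                pos = int(rng.integers(150, max(151, length - 150)))
                ref, alt = self._draw_alt(rng, cid, pos)
                self.conversion_sites.append((cid, pos))
                emit(off, cid, pos, ref, alt, (1, 1))
            others = [o for o in cfg.offspring_ids if o != off]
            if others:
                for _ in range(cfg.het_decoys_per_offspring):
                    cid = inherited[int(rng.integers(len(inherited)))]
                    length = self.meta[cid].segment.length
                    pos = int(rng.integers(150, max(151, length - 150)))
                    ref, alt = self._draw_alt(rng, cid, pos)
                    other = others[int(rng.integers(len(others)))]
                    self.het_decoy_sites[(cid, pos)] = other
                    emit(off, cid, pos, ref, alt, (1, 1))
                    emit(other, cid, pos, ref, alt, (0, 1), alt_frac=0.5)
        return out

    def conversion_mask(self) -> ConversionMask:
        return ConversionMask(getattr(self, "conversion_sites", []))

    # -- convenience ------------------------------------------------------
    @property
    def contig_parents(self) -> dict[str, str]:
        return {cid: m.parent for cid, m in self.meta.items()}

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.contig_id: c.length_bp for c in self.contigs}

    @property
    def contig_sequences(self) -> dict[str, str]:
        return {c.contig_id: c.sequence for c in self.contigs if c.sequence}

    def parent_contigs(self, parent: str) -> list[ContigRecord]:
        return [c for c in self.contigs if c.parent_of_origin == parent]


def simulate_pedigree(config: SimConfig) -> PedigreeSimulation:
    return PedigreeSimulation(config).generate()


# ---------------------------------------------------------------------------
# end-to-end benchmark harnesses
# ---------------------------------------------------------------------------

def classification_accuracy(sim: PedigreeSimulation,
                            zygosity: Mapping[str, ZygosityCall]) -> tuple[float, int]:
    """Accuracy of non-bubble contig classification against truth labels."""
    want = {"het": CAT_BUBBLE_LIKE, "hom": CAT_TRUE_NON_BUBBLE}
    classes = {c.contig_id: c.assembler_class for c in sim.contigs}
    n = ok = 0
    for cid, z in zygosity.items():
        if classes[cid] != NON_BUBBLE:
            continue
        n += 1
        if z.category == want[sim.truth.true_zygosity[cid]]:
            ok += 1
    return (ok / n if n else float("nan")), n


def inheritance_error_rate(sim: PedigreeSimulation, offspring_id: str,
                           final_calls: Mapping[str, object]) -> tuple[float, float, int]:
    """(error rate over resolved contigs, unresolved fraction, n resolved)."""
    n_res = n_err = n_unres = 0
    for cid, call in final_calls.items():
        state = call.state
        if state == UNRESOLVED:
            n_unres += 1
            continue
        n_res += 1
        if state != sim.true_inheritance_state(offspring_id, cid):
            n_err += 1
    total = n_res + n_unres
    return (n_err / n_res if n_res else float("nan"),
            n_unres / total if total else float("nan"), n_res)


def expected_callable_bp(sim: PedigreeSimulation, offspring_id: str,
                         end_trim: int = 100) -> int:
    """Closed-form callable expectation from the truth records.

    Truth-inherited phased contigs contribute length minus the end trims;
    at shared-ancestry segments a lone inherited shared allele contributes
    half its length and a doubly-inherited one nothing; homozygous contigs
    are confounded cross-parent pairs (both always inherited) and drop out.
    The stochastic 3x depth cap removes a negligible expected fraction and
    is not modelled.
    """
    total = 0
    unphased = 0
    seen_shared: set[int] = set()
    for cid, meta in sim.meta.items():
        if meta.hap is None:
            continue
        seg = meta.segment
        if seg.shared and meta.hap == 0:
            if seg.index in seen_shared:
                continue
            seen_shared.add(seg.index)
            hm = sim.truth.transmitted[(offspring_id, "maternal", seg.index)]
            hp = sim.truth.transmitted[(offspring_id, "paternal", seg.index)]
            if (hm == 0) != (hp == 0):  # lone inherited shared allele -> unphased
                unphased += seg.length
            continue
        if sim.true_inheritance_state(offspring_id, cid) != INHERITED:
            continue
        total += max(0, seg.length - 2 * end_trim)
    return total + unphased // 2


@dataclass
class BenchmarkReport:
    classification_accuracy: float
    n_classified: int
    inheritance_error_rate: float
    unresolved_fraction: float
    n_resolved: int
    callable_fraction: float
    callable_bp: dict[str, int]
    fnr: float
    mu_hat: float
    mu_true: float
    mu_ci: tuple[float, float]
    n_dnm_detected: int
    n_dnm_spiked: int
    positive_control_fraction: float
    per_offspring_error: dict[str, float]
    n_pzm_detected: int = 0
    n_pzm_spiked: int = 0
    pzm_vaf_mae: float = float("nan")


def run_pipeline(sim: PedigreeSimulation):
    """Classification + inheritance + callable for a generated pedigree."""
    zygosity: dict[str, ZygosityCall] = {}
    thresholds = {}
    for parent, pid in (("maternal", MOTHER), ("paternal", FATHER)):
        calls, thr = pipeline.classify_assembly(
            sim.parent_contigs(parent), sim.self_tracks[pid], sim.self_paf[parent])
        thresholds[parent] = thr
        for z in calls:
            zygosity[z.contig_id] = z
    scores = pipeline.compute_parental_scores(
        sim.combined_tracks[MOTHER], sim.combined_tracks[FATHER])
    similar_pairs = find_similar_allele_pairs(
        sim.cross_paf, scores, [c for c, m in sim.meta.items() if m.parent == "maternal"])
    inheritance = {}
    mean_depths = {}
    callables = {}
    for off in sim.config.offspring_ids:
        final, mdepth = pipeline.infer_offspring(
            off, sim.combined_tracks[off], sim.combined_tracks[MOTHER],
            sim.combined_tracks[FATHER], sim.contig_parents, zygosity, scores)
        inheritance[off] = final
        mean_depths[off] = mdepth
        callables[off] = pipeline.build_callable(
            off, final, zygosity, similar_pairs, sim.combined_tracks[off],
            mdepth, sim.contig_lengths, scores)
    return zygosity, thresholds, scores, similar_pairs, inheritance, mean_depths, callables


def run_benchmarks(config: SimConfig, artifacts: Optional[dict] = None) -> BenchmarkReport:
    """Generate a pedigree, run the full pipeline, score against truth.

    The FNR is estimated from the first offspring's spikes (mirroring the
    strategy of spiking selected individuals) and applied to a rate
    estimate computed from the remaining offspring when there are several.
    When ``artifacts`` is given, intermediate objects (simulation, zygosity,
    inheritance, callable sets, retained records ...) are stored in it.
    """
    sim = simulate_pedigree(config)
    zygosity, thresholds, scores, similar_pairs, inheritance, _mdepths, callables = run_pipeline(sim)

    acc, n_classified = classification_accuracy(sim, zygosity)
    per_off_err = {}
    errs, unres, n_res_total = [], [], 0
    for off in config.offspring_ids:
        e, u, n_res = inheritance_error_rate(sim, off, inheritance[off])
        per_off_err[off] = e
        errs.append(e)
        unres.append(u)
        n_res_total += n_res
    callable_bp = {o: callables[o].total_bp for o in config.offspring_ids}
    callable_fraction = float(np.mean([
        bp / (2 * config.genome_length_bp) for bp in callable_bp.values()]))

    sim.spike_mutations(callables)
    observations = sim.make_observations()
    mask = sim.conversion_mask()
    all_gts: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
    for off in config.offspring_ids:
        for caller_obs in observations[off].values():
            for obs in caller_obs:
                call = obs.samples.get(off)
                if call and call.genotype:
                    all_gts.setdefault((obs.contig_id, obs.pos), {})[off] = call.genotype

    detected: dict[str, list[DnmRecord]] = {}
    for off in config.offspring_ids:
        detected[off] = pipeline.call_dnms(
            off, observations[off][CALLER_PILEUP], observations[off][CALLER_HAPLOTYPE],
            callables[off], all_gts, mask, sim.contig_parents, scores)

    truth_sites = {(m.offspring_id, m.contig_id, m.pos, m.alt_base) for m in sim.truth.dnms}
    spiked_by_off = {o: sum(1 for m in sim.truth.dnms if m.offspring_id == o)
                     for o in config.offspring_ids}
    detected_true_by_off = {
        o: sum(1 for r in detected[o] if (o, r.contig_id, r.pos, r.alt_base) in truth_sites)
        for o in config.offspring_ids}

    fnr_off = config.offspring_ids[0]
    fnr = false_negative_rate(detected_true_by_off[fnr_off], max(1, spiked_by_off[fnr_off]))
    rate_off = config.offspring_ids[1:] or config.offspring_ids
    n_det = sum(len(detected[o]) for o in rate_off)
    L = sum(callable_bp[o] for o in rate_off)
    est = mutation_rate(n_det, L, fnr)
    n_spiked = sum(spiked_by_off[o] for o in rate_off)
    mu_true = n_spiked / L if L else float("nan")

    # postzygotic mutation recovery
    alt_depths: dict[tuple[str, int], dict[str, int]] = {}
    for off in config.offspring_ids:
        for caller_obs in observations[off].values():
            for obs in caller_obs:
                call = obs.samples.get(off)
                if call and call.allele_depths and len(call.allele_depths) > 1:
                    alt_depths.setdefault((obs.contig_id, obs.pos), {})[off] = call.allele_depths[1]
    high_sim = {cid for cid, s in scores.items() if s > 0.5}
    pzm_truth = {(m.offspring_id, m.contig_id, m.pos): m for m in sim.truth.pzms}
    n_pzm_det = 0
    vaf_err: list[float] = []
    pzms_by_off: dict[str, list] = {}
    from .variant_filter import indel_positions_from, merge_caller_calls
    for off in config.offspring_ids:
        partners = pipeline.allelic_partner_map(sim.cross_paf, sim.contig_parents, inheritance[off])
        merged = merge_caller_calls(
            observations[off][CALLER_PILEUP], observations[off][CALLER_HAPLOTYPE], high_sim)
        pzms = pzm_filter(
            merged, callables[off], all_gts, alt_depths, mask,
            indel_positions_from(merged), off, MOTHER, FATHER,
            sim.contig_parents, partners, sim.combined_tracks[off])
        pzms_by_off[off] = pzms
        for r in pzms:
            truth_rec = pzm_truth.get((off, r.contig_id, r.pos))
            if truth_rec is not None:
                n_pzm_det += 1
                vaf_err.append(abs(r.vaf - (truth_rec.true_vaf or 0.0)))

    pos_ctrl = pipeline.bubble_positive_control(
        sim.parent_contigs("maternal"), sim.self_tracks[MOTHER],
        sim.self_paf["maternal"], thresholds["maternal"])

    if artifacts is not None:
        artifacts.update(
            sim=sim, zygosity=zygosity, thresholds=thresholds, scores=scores,
            similar_pairs=similar_pairs, inheritance=inheritance,
            callables=callables, observations=observations, mask=mask,
            all_gts=all_gts, detected=detected, pzms_detected=pzms_by_off,
        )

    return BenchmarkReport(
        classification_accuracy=acc,
        n_classified=n_classified,
        inheritance_error_rate=float(np.mean(errs)),
        unresolved_fraction=float(np.mean(unres)),
        n_resolved=n_res_total,
        callable_fraction=callable_fraction,
        callable_bp=callable_bp,
        fnr=fnr,
        mu_hat=est.mu,
        mu_true=mu_true,
        mu_ci=(est.ci_low, est.ci_high),
        n_dnm_detected=n_det,
        n_dnm_spiked=n_spiked,
        positive_control_fraction=pos_ctrl,
        per_offspring_error=per_off_err,
        n_pzm_detected=n_pzm_det,
        n_pzm_spiked=len(sim.truth.pzms),
        pzm_vaf_mae=float(np.mean(vaf_err)) if vaf_err else float("nan"),
    )


# ---------------------------------------------------------------------------
# streamlined mutation-rate recovery study
# ---------------------------------------------------------------------------

def mu_recovery_study(
    n_replicates: int = 100,
    mu_star: float = 1e-6,
    genome_length_bp: int = 10_000_000,
    n_offspring: int = 30,
    callable_fraction: float = 0.35,
    contig_length_bp: int = 5_000,
    depth_mean: float = 80.0,
    low_qual_fraction: float = 0.03,
    caller_miss_rate: float = 0.01,
    fnr_spike_count: int = 500,
    seed: int = 0,
) -> dict:
    """Repeated spike -> detect -> estimate trials for CI calibration.

    Each replicate spikes Poisson(mu* x callable length) mutations per
    offspring onto a fixed callable geometry, pushes them through the
    observation-noise model and the DNM filter chain, estimates the FNR
    from an independent spike run (the spike-in strategy of the detection
    pipeline), and forms the corrected rate with its exact Poisson CI.
    Returns per-replicate estimates and the fraction of CIs covering mu*.
    """
    from .core_io import ConversionMask as _Mask
    from .variant_filter import dnm_filter

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D75]))
    diploid = 2 * genome_length_bp
    per_off_callable = callable_fraction * diploid
    usable = contig_length_bp - 200  # end trims
    n_contigs = int(round(per_off_callable / usable))
    contig_ids = [f"c{i}" for i in range(n_contigs)]
    contig_parents = {c: ("maternal" if i % 2 == 0 else "paternal")
                      for i, c in enumerate(contig_ids)}
    cset = CallableSet("off")
    for c in contig_ids:
        cset.phased_intervals[c] = [(100, contig_length_bp - 100)]
    L_call = cset.total_bp
    mask = _Mask([])

    def detect(n_spiked: int, off: str) -> int:
        obs = []
        cidx = rng.integers(0, n_contigs, size=n_spiked)
        poss = rng.integers(100, contig_length_bp - 100, size=n_spiked)
        for ci, pos in zip(cidx, poss):
            if rng.random() < caller_miss_rate:
                continue
            dp_off = int(rng.poisson(depth_mean / 2))
            dp_par = int(rng.poisson(depth_mean / 2))
            qual = (float(rng.uniform(100, 219)) if rng.random() < low_qual_fraction
                    else float(rng.uniform(230, 600)))
            obs.append(VariantObservation(
                contig_ids[ci], int(pos), "A", ("G",), qual, CALLER_PILEUP,
                {
                    off: SampleCall((1, 1), dp_off, (0, dp_off)),
                    MOTHER: SampleCall((0, 0), dp_par, (dp_par, 0)),
                    FATHER: SampleCall((0, 0), dp_par, (dp_par, 0)),
                },
            ))
        recs = dnm_filter(obs, cset, {}, set(), mask, offspring_id=off,
                          mother_id=MOTHER, father_id=FATHER,
                          contig_parents=contig_parents)
        return len(recs)

    covered = 0
    mus = []
    for _ in range(n_replicates):
        n_det_fnr = detect(fnr_spike_count, "fnr_off")
        fnr = false_negative_rate(n_det_fnr, fnr_spike_count)
        n_total = 0
        for _ in range(n_offspring):
            n_spiked = int(rng.poisson(mu_star * L_call))
            n_total += detect(n_spiked, "off")
        est = mutation_rate(n_total, L_call * n_offspring, fnr)
        mus.append(est.mu)
        if est.ci_low <= mu_star <= est.ci_high:
            covered += 1
    return {
        "coverage": covered / n_replicates,
        "mu_star": mu_star,
        "mu_mean": float(np.mean(mus)),
        "n_replicates": n_replicates,
        "callable_per_offspring_bp": L_call,
    }
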