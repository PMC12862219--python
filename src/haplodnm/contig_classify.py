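"""Zygosity classification of assembler contigs.

Allele-aware assemblers emit heterozygous regions as "bubble" contig pairs
and nominally homozygous regions as "non-bubble" contigs, but the non-bubble
set is in practice a mixture of homozygous sequence and unresolved
heterozygous alleles.  This module reclassifies non-bubble contigs into
bubble-like (heterozygous), true non-bubble (homozygous) and uncertain,
combining two lines of evidence:

* the contig-level mean read depth of the parent's own reads mapped back to
  its assembly, which is bimodal (haploid peak = heterozygous contigs,
  diploid peak = homozygous contigs); and
* reciprocal-best-hit (RBH) self-alignment: a heterozygous contig has a
  high-coverage, high-identity counterpart elsewhere in the assembly,
  whereas a homozygous contig has none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .core_io import (
    BUBBLE_PRIMARY,
    BUBBLE_SECONDARY,
    ContigRecord,
    DepthTrack,
    PafRecord,
)

CAT_BUBBLE = "bubble"
CAT_BUBBLE_LIKE = "bubble_like"
CAT_TRUE_NON_BUBBLE = "true_non_bubble"
CAT_UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class DepthThresholds:
    """Depth windows (in x coverage) separating haploid from diploid contigs."""

    het_low: float
    het_high: float
    hom_high: float

    def __post_init__(self) -> None:
        if not (0 < self.het_low < self.het_high < self.hom_high):
            raise ValueError("need 0 < het_low < het_high < hom_high")


@dataclass
class ZygosityCall:
    contig_id: str
    category: str
    mean_depth: float
    rbh_partner: Optional[str] = None
    rbh_coverage: Optional[float] = None
    rbh_identity: Optional[float] = None


@dataclass(frozen=True)
class RbhStats:
    coverage: float
    identity: float
    n_matches: int


def contig_mean_depth(track: DepthTrack) -> float:
    """Mean per-base depth across the contig length."""
    return track.mean()


def default_thresholds(parent_mean_depth: float) -> DepthThresholds:
    """Depth thresholds scaled linearly from an 80x calibration.

    At 80x parental coverage the windows are exactly [10, 50] for single-
    haplotype (heterozygous) contigs and (50, 100] for homozygous contigs;
    other coverages scale the windows proportionally.
    """
    if parent_mean_depth <= 0:
        raise ValueError("parent_mean_depth must be positive")
    f = parent_mean_depth / 80.0
    return DepthThresholds(het_low=10.0 * f, het_high=50.0 * f, hom_high=100.0 * f)


def _merged_span(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        if s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def qualifying_pairs(
    alignments: Iterable[PafRecord],
    min_coverage: float = 0.7,
    min_identity: float = 0.7,
) -> dict[tuple[str, str], RbhStats]:
    """Contig pairs passing the coverage and identity filters.

    Alignment blocks between the same two contigs are aggregated: identity is
    sum(n_matches)/sum(block_len) over all blocks of the pair, and coverage is
    the merged aligned span divided by sequence length, taken as the minimum
    of the query-side and target-side values so that a short contig contained
    in a long one cannot qualify asymmetrically.  Keys are sorted (a, b)
    tuples; self-hits are ignored.
    """
    spans: dict[frozenset, dict[str, list[tuple[int, int]]]] = {}
    matches: dict[frozenset, int] = {}
    blocks: dict[frozenset, int] = {}
    lengths: dict[str, int] = {}
    for rec in alignments:
        if rec.qname == rec.tname:
            continue
        key = frozenset((rec.qname, rec.tname))
        pair_spans = spans.setdefault(key, {})
        pair_spans.setdefault(rec.qname, []).append((rec.qstart, rec.qend))
        pair_spans.setdefault(rec.tname, []).append((rec.tstart, rec.tend))
        matches[key] = matches.get(key, 0) + rec.n_matches
        blocks[key] = blocks.get(key, 0) + rec.block_len
        lengths[rec.qname] = rec.qlen
        lengths[rec.tname] = rec.tlen

    out: dict[tuple[str, str], RbhStats] = {}
    for key in spans:
        a, b = sorted(key)
        cov = min(
            _merged_span(spans[key][a]) / lengths[a],
            _merged_span(spans[key][b]) / lengths[b],
        )
        ident = matches[key] / blocks[key] if blocks[key] else 0.0
        if cov >= min_coverage and ident >= min_identity:
            out[(a, b)] = RbhStats(coverage=cov, identity=ident, n_matches=matches[key])
    return out


def rbh_pairs(
    alignments: Iterable[PafRecord],
    min_coverage: float = 0.7,
    min_identity: float = 0.7,
) -> dict[tuple[str, str], RbhStats]:
    """Reciprocal best hits from an all-vs-all self-alignment.

    A contig's best hit is the qualifying pair maximising total matches; a
    tie between two equal best hits rejects the pair (conservative reading
    of "reciprocal best").  Keys of the returned mapping are sorted (a, b)
    tuples.
    """
    qualifying = qualifying_pairs(alignments, min_coverage, min_identity)

    best: dict[str, Optional[str]] = {}
    best_matches: dict[str, int] = {}
    for (a, b), stats in qualifying.items():
        for focal, other in ((a, b), (b, a)):
            prev = best_matches.get(focal)
            if prev is None or stats.n_matches > prev:
                best[focal] = other
                best_matches[focal] = stats.n_matches
            elif stats.n_matches == prev:
                best[focal] = None  # tie -> no reciprocal best

    out: dict[tuple[str, str], RbhStats] = {}
    for (a, b), stats in qualifying.items():
        if best.get(a) == b and best.get(b) == a:
            out[(a, b)] = stats
    return out


def classify_contigs(
    contigs: Iterable[ContigRecord],
    mean_depths: Mapping[str, float],
    rbh: Mapping[tuple[str, str], RbhStats],
    thresholds: DepthThresholds,
) -> list[ZygosityCall]:
    """Assign every contig exactly one zygosity category.

    Assembler bubble contigs keep category ``bubble``.  Non-bubble contigs
    are partitioned by depth into candidate heterozygous ([het_low,
    het_high]) and candidate homozygous ((het_high, hom_high]); candidate-het
    RBH pairs whose two members are both candidate het become ``bubble_like``
    pairs, candidate-hom contigs with any qualifying RBH are demoted to
    ``uncertain``, candidate-hom contigs without one are ``true_non_bubble``,
    and everything else is ``uncertain``.
    """
    contigs = list(contigs)
    for c in contigs:
        if c.contig_id not in mean_depths:
            raise KeyError(f"no mean depth for contig {c.contig_id}")

    partner_of: dict[str, tuple[str, RbhStats]] = {}
    for (a, b), stats in rbh.items():
        partner_of[a] = (b, stats)
        partner_of[b] = (a, stats)

    def is_cand_het(cid: str) -> bool:
        d = mean_depths[cid]
        return thresholds.het_low <= d <= thresholds.het_high

    def is_cand_hom(cid: str) -> bool:
        d = mean_depths[cid]
        return thresholds.het_high < d <= thresholds.hom_high

    non_bubble_ids = {
        c.contig_id for c in contigs
        if c.assembler_class not in (BUBBLE_PRIMARY, BUBBLE_SECONDARY)
    }

    calls: list[ZygosityCall] = []
    for c in contigs:
        cid = c.contig_id
        depth = float(mean_depths[cid])
        if c.assembler_class in (BUBBLE_PRIMARY, BUBBLE_SECONDARY):
            calls.append(ZygosityCall(cid, CAT_BUBBLE, depth, rbh_partner=c.partner_id))
            continue
        hit = partner_of.get(cid)
        if is_cand_het(cid):
            if (
                hit is not None
                and hit[0] in non_bubble_ids
                and is_cand_het(hit[0])
            ):
                calls.append(
                    ZygosityCall(
                        cid, CAT_BUBBLE_LIKE, depth,
                        rbh_partner=hit[0],
                        rbh_coverage=hit[1].coverage,
                        rbh_identity=hit[1].identity,
                    )
                )
            else:
                calls.append(ZygosityCall(cid, CAT_UNCERTAIN, depth))
        elif is_cand_hom(cid):
            if hit is not None:
                calls.append(
                    ZygosityCall(
                        cid, CAT_UNCERTAIN, depth,
                        rbh_partner=hit[0],
                        rbh_coverage=hit[1].coverage,
                        rbh_identity=hit[1].identity,
                    )
                )
            else:
                calls.append(ZygosityCall(cid, CAT_TRUE_NON_BUBBLE, depth))
        else:
            calls.append(ZygosityCall(cid, CAT_UNCERTAIN, depth))
    return calls
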