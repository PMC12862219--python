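"""Per-offspring callable genome: where a de novo mutation could be called.

The callable genome starts from the contigs an offspring inherited and
removes everything where a DNM call would be unreliable: contigs whose
parental origin is confounded by a near-identical allele in the other
parent (highly similar allele pairs, a signature of shared ancestry in
inbred pedigrees), contig ends (assembly/alignment error hotspots), and
positions whose depth exceeds three times the individual's average
(collapsed repeats).  When exactly one member of a highly similar
cross-parent allele pair is inherited, the contig stays callable but
unphased -- the offspring carries exactly one of two near-identical
alleles, so it contributes half its length to the callable size and its
mutations cannot be assigned a parental origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .contig_classify import CAT_UNCERTAIN, ZygosityCall, rbh_pairs
from .core_io import DepthTrack, PafRecord
from .inheritance import INHERITED, InheritanceCall

DEFAULT_END_TRIM = 100
DEFAULT_DEPTH_CAP_MULTIPLIER = 3.0


@dataclass(frozen=True)
class SimilarAllelePair:
    """Cross-parent RBH contig pair with parental similarity score > 0.5."""

    maternal_contig_id: str
    paternal_contig_id: str
    parental_similarity: float


@dataclass
class CallableSet:
    offspring_id: str
    phased_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    unphased_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    unphased_contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def unphased_contigs(self) -> set[str]:
        return set(self.unphased_contig_lengths)

    @property
    def phased_bp(self) -> int:
        return sum(e - s for ivs in self.phased_intervals.values() for s, e in ivs)

    @property
    def unphased_bp_contribution(self) -> int:
        return sum(self.unphased_contig_lengths.values()) // 2

    @property
    def total_bp(self) -> int:
        return self.phased_bp + self.unphased_bp_contribution

    def contains(self, contig_id: str, pos: int) -> bool:
        """Membership of a position in the callable set (phased or unphased)."""
        for ivs in (self.phased_intervals.get(contig_id), self.unphased_intervals.get(contig_id)):
            if ivs:
                for s, e in ivs:
                    if s <= pos < e:
                        return True
        return False

    def is_unphased(self, contig_id: str) -> bool:
        return contig_id in self.unphased_contig_lengths


def _subtract(intervals: list[tuple[int, int]], cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        segs = [(s, e)]
        for cs, ce in cuts:
            nxt = []
            for a, b in segs:
                if ce <= a or cs >= b:
                    nxt.append((a, b))
                else:
                    if a < cs:
                        nxt.append((a, cs))
                    if ce < b:
                        nxt.append((ce, b))
            segs = nxt
        out.extend(segs)
    return [iv for iv in out if iv[1] > iv[0]]


def find_similar_allele_pairs(
    cross_parent_paf: Iterable[PafRecord],
    parental_similarity_scores: Mapping[str, float],
    maternal_contigs: Iterable[str],
    min_coverage: float = 0.7,
    min_identity: float = 0.7,
    similarity_cutoff: float = 0.5,
) -> list[SimilarAllelePair]:
    """Cross-parent RBH pairs whose parental similarity exceeds the cutoff.

    The pair score is the larger of the two members' parental similarity
    scores: if either member's read profile is parent-ambiguous, the locus
    is treated as a highly similar allele pair.
    """
    maternal = set(maternal_contigs)
    pairs = rbh_pairs(cross_parent_paf, min_coverage, min_identity)
    out: list[SimilarAllelePair] = []
    for (a, b), _stats in pairs.items():
        if (a in maternal) == (b in maternal):
            continue  # not a cross-parent pair
        m, p = (a, b) if a in maternal else (b, a)
        score = max(
            float(parental_similarity_scores.get(m, 0.0)),
            float(parental_similarity_scores.get(p, 0.0)),
        )
        if score > similarity_cutoff:
            out.append(SimilarAllelePair(m, p, score))
    return out


def cross_parent_homologs(
    cross_parent_paf: Iterable[PafRecord],
    maternal_contigs: Iterable[str],
    min_coverage: float = 0.7,
    min_identity: float = 0.7,
) -> dict[str, str]:
    """RBH map contig -> its allelic counterpart in the other parent."""
    maternal = set(maternal_contigs)
    out: dict[str, str] = {}
    for (a, b) in rbh_pairs(cross_parent_paf, min_coverage, min_identity):
        if (a in maternal) != (b in maternal):
            out[a] = b
            out[b] = a
    return out


def callable_set(
    offspring_id: str,
    inheritance_calls: Mapping[str, InheritanceCall],
    zygosity: Mapping[str, ZygosityCall],
    similar_pairs: Iterable[SimilarAllelePair],
    depth_tracks: Mapping[str, DepthTrack],
    offspring_mean_depth: float,
    contig_lengths: Mapping[str, int],
    parental_similarity_scores: Optional[Mapping[str, float]] = None,
    end_trim: int = DEFAULT_END_TRIM,
    depth_cap_multiplier: float = DEFAULT_DEPTH_CAP_MULTIPLIER,
) -> CallableSet:
    """Build one offspring's callable set from finalized inheritance calls.

    Filters, in order (the order is fixed for reproducibility; the result is
    a set intersection and does not depend on it): keep inherited contigs;
    drop both members of a highly similar allele pair when both are
    inherited, keep a lone inherited member as unphased; drop high-
    similarity contigs without a cross-parent homolog; trim ``end_trim`` bp
    from each contig end; drop positions with depth above
    ``depth_cap_multiplier`` times the offspring's mean depth.
    """
    scores = parental_similarity_scores or {}
    inherited = set()
    for cid, call in inheritance_calls.items():
        if cid not in contig_lengths:
            raise KeyError(f"inheritance call references unknown contig {cid}")
        if call.state == INHERITED:
            inherited.add(cid)

    pair_members: dict[str, SimilarAllelePair] = {}
    for pair in similar_pairs:
        pair_members[pair.maternal_contig_id] = pair
        pair_members[pair.paternal_contig_id] = pair

    phased: set[str] = set()
    unphased: set[str] = set()
    for cid in inherited:
        z = zygosity.get(cid)
        # uncertain contigs with ambiguous parental origin are excluded
        if z is not None and z.category == CAT_UNCERTAIN and float(scores.get(cid, 0.0)) > 0.5:
            continue
        pair = pair_members.get(cid)
        if pair is not None:
            other = (
                pair.paternal_contig_id
                if cid == pair.maternal_contig_id
                else pair.maternal_contig_id
            )
            if other in inherited:
                continue  # both alleles of a confounded pair: drop both
            unphased.add(cid)
            continue
        if float(scores.get(cid, 0.0)) > 0.5:
            # parent-ambiguous but no identifiable homolog: cannot tell
            # whether the other parent transmitted its copy -> drop
            continue
        phased.add(cid)

    cap = depth_cap_multiplier * offspring_mean_depth
    result = CallableSet(offspring_id)
    for cid in sorted(phased | unphased):
        length = contig_lengths[cid]
        base = [(end_trim, length - end_trim)]
        if base[0][1] <= base[0][0]:
            intervals: list[tuple[int, int]] = []
        else:
            track = depth_tracks.get(cid)
            cuts = track.high_depth_intervals(cap) if track is not None else []
            intervals = _subtract(base, cuts)
        if cid in unphased:
            result.unphased_intervals[cid] = intervals
            result.unphased_contig_lengths[cid] = length
        else:
            result.phased_intervals[cid] = intervals
    return result
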