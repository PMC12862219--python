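"""Two-stage inference of which parental contigs an offspring inherited.

Offspring reads are aligned against the combined parental reference (both
parents' assemblies).  For every contig, the offspring's binned read-depth
profile is compared with each parent's profile on the same contig: a contig
that was transmitted attracts the offspring's reads and its depth profile
resembles the parent-of-origin's, while a non-transmitted allele collects
(almost) no reads.

Stage 1 decides each contig independently from a low-depth rule plus the
profile-similarity comparison.  Stage 2 enforces Mendelian consistency
within bubble pairs (a diploid offspring inherits exactly one allele per
locus per parent) and uses the "parental similarity score" -- the same
profile similarity computed between the two parents' own read profiles on a
contig -- to detect contigs whose parental origin is unresolvable because
the parents carry near-identical alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core_io import DepthTrack
from .contig_classify import (
    CAT_BUBBLE,
    CAT_BUBBLE_LIKE,
    CAT_TRUE_NON_BUBBLE,
    CAT_UNCERTAIN,
    ZygosityCall,
)

INHERITED = "inherited"
NOT_INHERITED = "not_inherited"
UNRESOLVED = "unresolved"

BASIS_LOW_DEPTH = "low_depth"
BASIS_SIMILARITY = "similarity"
BASIS_PARTNER_FORCED = "partner_forced"
BASIS_PARENTAL_SIMILARITY = "parental_similarity"
BASIS_HOMOZYGOUS_ALWAYS = "homozygous_always"
BASIS_HIGH_PARENTAL_SIMILARITY = "high_parental_similarity"

DEFAULT_BIN_SIZE = 50
SIMILARITY_CUTOFF = 0.5


@dataclass
class DepthVector:
    """Per-contig depth profile of one individual: mean depth per 50-bp bin."""

    contig_id: str
    individual_id: str
    bin_size_bp: int
    values: np.ndarray

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    cosine_part: float
    jaccard_part: float
    weight_nonzero: float
    weight_zero: float


@dataclass
class InheritanceCall:
    offspring_id: str
    contig_id: str
    state: str
    stage: int
    basis: str
    similarity_to_origin: Optional[float] = None
    similarity_to_other: Optional[float] = None
    parental_similarity: Optional[float] = None


def bin_depths(track: DepthTrack, bin_size: int = DEFAULT_BIN_SIZE) -> DepthVector:
    """Mean depth per ``bin_size`` window; a trailing partial bin is dropped."""
    n_bins = track.length // bin_size
    if n_bins < 1:
        raise ValueError(
            f"{track.contig_id}: contig shorter than one {bin_size}-bp bin cannot be scored"
        )
    per_base = track.to_array()[: n_bins * bin_size]
    values = per_base.reshape(n_bins, bin_size).mean(axis=1)
    return DepthVector(track.contig_id, track.individual_id, bin_size, values)


def depth_similarity(u: DepthVector, v: DepthVector) -> SimilarityScore:
    """Weighted cosine + zero-pattern Jaccard similarity of two profiles.

    Bins where both profiles are positive contribute a cosine similarity;
    bins where at least one profile is zero contribute a Jaccard similarity
    of the zero patterns (zero-in-both / zero-in-at-least-one), so identical
    uncovered regions score 1 and disjoint coverage scores 0.  The two parts
    are weighted by their bin-count proportions.
    """
    if u.values.shape != v.values.shape:
        raise ValueError(
            f"bin-count mismatch on {u.contig_id}: {u.values.size} vs {v.values.size}"
        )
    a = u.values
    b = v.values
    n = a.size
    both_pos = (a > 0) & (b > 0)
    n_nz = int(both_pos.sum())
    n_z = n - n_nz
    if n_nz:
        ua = a[both_pos]
        vb = b[both_pos]
        # cosine is scale-invariant per vector; normalising by each max
        # guards against under/overflow at extreme depths
        ua = ua / ua.max()
        vb = vb / vb.max()
        cosine = float(np.dot(ua, vb) / (np.linalg.norm(ua) * np.linalg.norm(vb)))
        cosine = min(1.0, max(0.0, cosine))
    else:
        cosine = 1.0  # carries zero weight
    if n_z:
        zero_both = int(((a == 0) & (b == 0)).sum())
        jaccard = zero_both / n_z
    else:
        jaccard = 1.0  # carries zero weight
    w_nz = n_nz / n
    w_z = n_z / n
    return SimilarityScore(
        value=w_nz * cosine + w_z * jaccard,
        cosine_part=cosine,
        jaccard_part=jaccard,
        weight_nonzero=w_nz,
        weight_zero=w_z,
    )


def parental_similarity_score(
    maternal_track: DepthTrack,
    paternal_track: DepthTrack,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> float:
    """Profile similarity of the two parents' reads on the same contig.

    A score above 0.5 means the parents' reads are near-interchangeable on
    this contig, so offspring inheritance calls there are unreliable.
    """
    if maternal_track.contig_id != paternal_track.contig_id:
        raise ValueError("parental tracks must be on the same contig")
    u = bin_depths(maternal_track, bin_size)
    v = bin_depths(paternal_track, bin_size)
    return depth_similarity(u, v).value


def reference_mean_depth(tracks: list[DepthTrack], min_contig_depth: float = 10.0) -> float:
    """Length-weighted mean depth of an individual over covered contigs.

    Contigs whose raw mean depth falls below ``min_contig_depth`` (the
    absolute low-depth floor) are excluded, so non-inherited alleles at ~0x
    do not drag the statistic down; the result approximates the individual's
    haplotype-dose coverage on the contigs it actually carries.
    """
    num = 0.0
    den = 0
    for t in tracks:
        m = t.mean()
        if m >= min_contig_depth:
            num += m * t.length
            den += t.length
    if den == 0:
        raise ValueError("no contig passes the minimum depth floor")
    return num / den


def stage1_call(
    offspring_vector: DepthVector,
    origin_parent_vector: DepthVector,
    other_parent_vector: DepthVector,
    offspring_genome_mean_depth: float,
    low_depth_floor: float = 10.0,
) -> InheritanceCall:
    """Per-contig inheritance call from depth alone.

    A contig with offspring depth below max(10, mean/4) is non-inherited;
    otherwise the contig is inherited iff the offspring profile is more
    similar to the parent-of-origin's profile than to the other parent's.
    An exact similarity tie is left unresolved for stage 2.
    """
    if offspring_genome_mean_depth <= 0:
        raise ValueError("offspring_genome_mean_depth must be positive")
    cid = offspring_vector.contig_id
    oid = offspring_vector.individual_id
    threshold = max(low_depth_floor, offspring_genome_mean_depth / 4.0)
    if offspring_vector.mean() < threshold:
        return InheritanceCall(oid, cid, NOT_INHERITED, stage=1, basis=BASIS_LOW_DEPTH)
    s_origin = depth_similarity(offspring_vector, origin_parent_vector).value
    s_other = depth_similarity(offspring_vector, other_parent_vector).value
    if s_origin > s_other:
        state = INHERITED
    elif s_origin < s_other:
        state = NOT_INHERITED
    else:
        state = UNRESOLVED
    return InheritanceCall(
        oid, cid, state, stage=1, basis=BASIS_SIMILARITY,
        similarity_to_origin=s_origin, similarity_to_other=s_other,
    )


def _finalize(call: InheritanceCall, state: str, basis: str, score: Optional[float]) -> InheritanceCall:
    return InheritanceCall(
        call.offspring_id, call.contig_id, state, stage=2, basis=basis,
        similarity_to_origin=call.similarity_to_origin,
        similarity_to_other=call.similarity_to_other,
        parental_similarity=score,
    )


def stage2_resolve(
    stage1_calls: Mapping[str, InheritanceCall],
    parental_similarity_scores: Mapping[str, float],
    zygosity: Mapping[str, ZygosityCall],
    similarity_cutoff: float = SIMILARITY_CUTOFF,
) -> dict[str, InheritanceCall]:
    """Refine stage-1 calls with pair logic and parental-similarity scores.

    Rules, in order per locus:

    * true non-bubble (homozygous) contigs are always inherited;
    * a bubble/bubble-like pair with both parental-similarity scores above
      the cutoff is unresolvable (both members ``unresolved``);
    * within a pair, a low-depth member forces its partner to be inherited;
    * otherwise the member whose score is below the cutoff is trusted; when
      both are trustworthy and agree on "inherited" (or on "not inherited"),
      the member with the LOWER score wins (is kept / force-inherited);
    * uncertain non-bubble contigs keep their stage-1 call unless their score
      exceeds the cutoff, in which case they are unresolved and excluded
      downstream.
    """
    final: dict[str, InheritanceCall] = {}
    done: set[str] = set()

    def score(cid: str) -> float:
        return float(parental_similarity_scores.get(cid, 0.0))

    for cid, call in stage1_calls.items():
        if cid in done:
            continue
        z = zygosity.get(cid)
        if z is None:
            raise KeyError(f"contig {cid} missing from zygosity table")
        if z.category == CAT_TRUE_NON_BUBBLE:
            final[cid] = _finalize(call, INHERITED, BASIS_HOMOZYGOUS_ALWAYS, score(cid))
            done.add(cid)
            continue
        if z.category == CAT_UNCERTAIN:
            if score(cid) > similarity_cutoff:
                final[cid] = _finalize(call, UNRESOLVED, BASIS_HIGH_PARENTAL_SIMILARITY, score(cid))
            else:
                final[cid] = _finalize(call, call.state, call.basis, score(cid))
            done.add(cid)
            continue
        # bubble or bubble-like: resolve the pair jointly
        partner = z.rbh_partner
        if partner is None or partner not in stage1_calls:
            raise ValueError(f"bubble contig {cid} has no partner call (partner={partner})")
        pz = zygosity.get(partner)
        if pz is None or (pz.rbh_partner != cid):
            raise ValueError(f"inconsistent partner ids for pair ({cid}, {partner})")
        a, b = cid, partner
        ca, cb = stage1_calls[a], stage1_calls[b]
        sa, sb = score(a), score(b)
        if sa > similarity_cutoff and sb > similarity_cutoff:
            final[a] = _finalize(ca, UNRESOLVED, BASIS_HIGH_PARENTAL_SIMILARITY, sa)
            final[b] = _finalize(cb, UNRESOLVED, BASIS_HIGH_PARENTAL_SIMILARITY, sb)
        elif ca.basis == BASIS_LOW_DEPTH and cb.basis == BASIS_LOW_DEPTH:
            # neither allele attracted reads: force-inherit the member whose
            # parental origin is the more distinguishable
            keep, drop = (a, b) if sa <= sb else (b, a)
            final[keep] = _finalize(stage1_calls[keep], INHERITED, BASIS_PARENTAL_SIMILARITY, score(keep))
            final[drop] = _finalize(stage1_calls[drop], NOT_INHERITED, BASIS_PARENTAL_SIMILARITY, score(drop))
        elif ca.basis == BASIS_LOW_DEPTH:
            final[a] = _finalize(ca, NOT_INHERITED, BASIS_LOW_DEPTH, sa)
            final[b] = _finalize(cb, INHERITED, BASIS_PARTNER_FORCED, sb)
        elif cb.basis == BASIS_LOW_DEPTH:
            final[b] = _finalize(cb, NOT_INHERITED, BASIS_LOW_DEPTH, sb)
            final[a] = _finalize(ca, INHERITED, BASIS_PARTNER_FORCED, sa)
        else:
            # both passed depth
            trusted = [c for c, s in ((a, sa), (b, sb)) if s <= similarity_cutoff]
            if len(trusted) == 1:
                t = trusted[0]
                o = b if t == a else a
                t_state = stage1_calls[t].state
                if t_state == INHERITED:
                    final[t] = _finalize(stage1_calls[t], INHERITED, BASIS_SIMILARITY, score(t))
                    final[o] = _finalize(stage1_calls[o], NOT_INHERITED, BASIS_PARTNER_FORCED, score(o))
                elif t_state == NOT_INHERITED:
                    final[t] = _finalize(stage1_calls[t], NOT_INHERITED, BASIS_SIMILARITY, score(t))
                    final[o] = _finalize(stage1_calls[o], INHERITED, BASIS_PARTNER_FORCED, score(o))
                else:  # stage-1 tie on the trusted member
                    keep, drop = (t, o) if score(t) <= score(o) else (o, t)
                    final[keep] = _finalize(stage1_calls[keep], INHERITED, BASIS_PARENTAL_SIMILARITY, score(keep))
                    final[drop] = _finalize(stage1_calls[drop], NOT_INHERITED, BASIS_PARENTAL_SIMILARITY, score(drop))
            else:
                sta, stb = ca.state, cb.state
                if sta == INHERITED and stb != INHERITED:
                    final[a] = _finalize(ca, INHERITED, BASIS_SIMILARITY, sa)
                    final[b] = _finalize(cb, NOT_INHERITED, BASIS_SIMILARITY, sb)
                elif stb == INHERITED and sta != INHERITED:
                    final[b] = _finalize(cb, INHERITED, BASIS_SIMILARITY, sb)
                    final[a] = _finalize(ca, NOT_INHERITED, BASIS_SIMILARITY, sa)
                else:
                    # both inherited, both not inherited, or ties: the member
                    # with the lower parental similarity score is inherited
                    keep, drop = (a, b) if sa <= sb else (b, a)
                    final[keep] = _finalize(stage1_calls[keep], INHERITED, BASIS_PARENTAL_SIMILARITY, score(keep))
                    final[drop] = _finalize(stage1_calls[drop], NOT_INHERITED, BASIS_PARENTAL_SIMILARITY, score(drop))
        done.add(a)
        done.add(b)
    return final


def check_pair_invariant(
    final_calls: Mapping[str, InheritanceCall],
    zygosity: Mapping[str, ZygosityCall],
) -> None:
    """Assert exactly one inherited member per resolvable bubble pair."""
    seen: set[str] = set()
    for cid, call in final_calls.items():
        z = zygosity[cid]
        if z.category not in (CAT_BUBBLE, CAT_BUBBLE_LIKE) or cid in seen:
            continue
        partner = z.rbh_partner
        if partner not in final_calls:
            continue
        seen.update((cid, partner))
        pc = final_calls[partner]
        if call.basis == BASIS_HIGH_PARENTAL_SIMILARITY and pc.basis == BASIS_HIGH_PARENTAL_SIMILARITY:
            continue
        states = sorted((call.state, pc.state))
        if states != [INHERITED, NOT_INHERITED]:
            raise AssertionError(
                f"pair ({cid}, {partner}) violates exactly-one-inherited: {states}"
            )
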