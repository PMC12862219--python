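"""Stage-level orchestration shared by the CLI and the benchmark harness.

Each function is a pure mapping from the upstream stage's artifacts to the
next stage's, mirroring how the stages hand off TSV/BED/VCF files on disk.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .callable_genome import CallableSet, SimilarAllelePair, callable_set
from .contig_classify import (
    CAT_BUBBLE,
    CAT_BUBBLE_LIKE,
    DepthThresholds,
    ZygosityCall,
    classify_contigs,
    default_thresholds,
    rbh_pairs,
)
from .core_io import (
    BUBBLE_PRIMARY,
    BUBBLE_SECONDARY,
    ContigRecord,
    ConversionMask,
    DepthTrack,
    PafRecord,
    VariantObservation,
)
from .inheritance import (
    InheritanceCall,
    bin_depths,
    depth_similarity,
    parental_similarity_score,
    reference_mean_depth,
    stage1_call,
    stage2_resolve,
)
from .variant_filter import (
    DnmRecord,
    FilterLog,
    dnm_filter,
    indel_positions_from,
    merge_caller_calls,
)


def estimate_parent_sequencing_depth(tracks: Iterable[DepthTrack]) -> float:
    """Estimate an individual's diploid sequencing depth from its assembly.

    Twice the length-weighted median of per-contig mean depths: on an
    allele-aware assembly most of the length is single-haplotype sequence
    covered at half the sequencing depth, so the weighted median sits on
    the haploid peak.
    """
    pairs = sorted((t.mean(), t.length) for t in tracks)
    total = sum(l for _, l in pairs)
    acc = 0
    for depth, length in pairs:
        acc += length
        if acc * 2 >= total:
            return 2.0 * depth
    raise ValueError("no depth tracks")


def classify_assembly(
    contigs: Sequence[ContigRecord],
    self_tracks: Mapping[str, DepthTrack],
    self_alignment: Sequence[PafRecord],
    parent_depth: Optional[float] = None,
) -> tuple[list[ZygosityCall], DepthThresholds]:
    """Run depth + RBH zygosity classification for one parent's assembly."""
    mean_depths = {cid: t.mean() for cid, t in self_tracks.items()}
    if parent_depth is None:
        parent_depth = estimate_parent_sequencing_depth(self_tracks.values())
    thresholds = default_thresholds(parent_depth)
    rbh = rbh_pairs(self_alignment)
    calls = classify_contigs(contigs, mean_depths, rbh, thresholds)
    return calls, thresholds


def bubble_positive_control(
    contigs: Sequence[ContigRecord],
    self_tracks: Mapping[str, DepthTrack],
    self_alignment: Sequence[PafRecord],
    thresholds: DepthThresholds,
) -> float:
    """Fraction of assembler bubble contigs re-identified as heterozygous.

    Bubble contigs are reliable heterozygous sequence, so pushing them
    through the same depth + RBH pipeline gives an internal positive
    control on the bubble-like category.
    """
    rbh = rbh_pairs(self_alignment)
    partner_of = {}
    for (a, b) in rbh:
        partner_of[a] = b
        partner_of[b] = a
    bubble = [c for c in contigs if c.assembler_class in (BUBBLE_PRIMARY, BUBBLE_SECONDARY)]
    if not bubble:
        return float("nan")
    ok = 0
    for c in bubble:
        d = self_tracks[c.contig_id].mean()
        if thresholds.het_low <= d <= thresholds.het_high and partner_of.get(c.contig_id) == c.partner_id:
            ok += 1
    return ok / len(bubble)


def compute_parental_scores(
    mother_tracks: Mapping[str, DepthTrack],
    father_tracks: Mapping[str, DepthTrack],
) -> dict[str, float]:
    """Parental similarity score per contig of the combined reference."""
    out = {}
    for cid, mt in mother_tracks.items():
        ft = father_tracks.get(cid)
        if ft is None:
            continue
        out[cid] = parental_similarity_score(mt, ft)
    return out


def infer_offspring(
    offspring_id: str,
    offspring_tracks: Mapping[str, DepthTrack],
    mother_tracks: Mapping[str, DepthTrack],
    father_tracks: Mapping[str, DepthTrack],
    contig_parents: Mapping[str, str],
    zygosity: Mapping[str, ZygosityCall],
    parental_scores: Mapping[str, float],
) -> tuple[dict[str, InheritanceCall], float]:
    """Stage-1 + stage-2 inheritance calls for one offspring.

    Returns the finalized per-contig calls and the offspring's reference
    mean depth (reused by the callable-genome depth cap).
    """
    mean_depth = reference_mean_depth(list(offspring_tracks.values()))
    stage1: dict[str, InheritanceCall] = {}
    for cid, otrack in offspring_tracks.items():
        mtrack = mother_tracks.get(cid)
        ftrack = father_tracks.get(cid)
        if mtrack is None or ftrack is None:
            continue
        ovec = bin_depths(otrack)
        mvec = bin_depths(mtrack)
        fvec = bin_depths(ftrack)
        if contig_parents[cid] == "maternal":
            origin_vec, other_vec = mvec, fvec
        else:
            origin_vec, other_vec = fvec, mvec
        stage1[cid] = stage1_call(ovec, origin_vec, other_vec, mean_depth)
    final = stage2_resolve(stage1, parental_scores, zygosity)
    return final, mean_depth


def build_callable(
    offspring_id: str,
    final_calls: Mapping[str, InheritanceCall],
    zygosity: Mapping[str, ZygosityCall],
    similar_pairs: Sequence[SimilarAllelePair],
    offspring_tracks: Mapping[str, DepthTrack],
    offspring_mean_depth: float,
    contig_lengths: Mapping[str, int],
    parental_scores: Mapping[str, float],
    end_trim: int = 100,
    depth_cap_multiplier: float = 3.0,
) -> CallableSet:
    return callable_set(
        offspring_id,
        final_calls,
        zygosity,
        similar_pairs,
        offspring_tracks,
        offspring_mean_depth,
        contig_lengths,
        parental_similarity_scores=parental_scores,
        end_trim=end_trim,
        depth_cap_multiplier=depth_cap_multiplier,
    )


def allelic_partner_map(
    cross_parent_paf: Sequence[PafRecord],
    contig_parents: Mapping[str, str],
    final_calls: Mapping[str, InheritanceCall],
) -> dict[str, str]:
    """For each inherited contig, the other parent's inherited allelic contig.

    Candidates are cross-parent contig pairs passing the alignment coverage
    and identity filters; among a contig's candidates the one the offspring
    actually inherited is its allelic counterpart (the denominator contig
    for postzygotic VAF computation).
    """
    from .contig_classify import qualifying_pairs
    from .inheritance import INHERITED

    candidates: dict[str, list[str]] = {}
    for (a, b) in qualifying_pairs(cross_parent_paf):
        if contig_parents.get(a) == contig_parents.get(b):
            continue
        candidates.setdefault(a, []).append(b)
        candidates.setdefault(b, []).append(a)
    out: dict[str, str] = {}
    for cid, cands in candidates.items():
        call = final_calls.get(cid)
        if call is None or call.state != INHERITED:
            continue
        inherited = [c for c in cands
                     if final_calls.get(c) is not None and final_calls[c].state == INHERITED]
        if len(inherited) == 1:
            out[cid] = inherited[0]
    return out


def call_dnms(
    offspring_id: str,
    pileup_calls: Sequence[VariantObservation],
    haplotype_calls: Sequence[VariantObservation],
    callable_set_: CallableSet,
    all_offspring_genotypes: Mapping[tuple[str, int], Mapping[str, tuple[int, int]]],
    conversion_mask: ConversionMask,
    contig_parents: Mapping[str, str],
    parental_scores: Mapping[str, float],
    mother_id: str = "mother",
    father_id: str = "father",
    log: Optional[FilterLog] = None,
    **filter_kwargs,
) -> list[DnmRecord]:
    """Merge the two callers' observations and apply the DNM criteria."""
    high_sim = {cid for cid, s in parental_scores.items() if s > 0.5}
    merged = merge_caller_calls(pileup_calls, haplotype_calls, high_sim)
    indels = indel_positions_from(merged)
    return dnm_filter(
        merged,
        callable_set_,
        all_offspring_genotypes,
        indels,
        conversion_mask,
        offspring_id=offspring_id,
        mother_id=mother_id,
        father_id=father_id,
        contig_parents=contig_parents,
        log=log,
        **filter_kwargs,
    )
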