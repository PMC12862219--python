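"""Candidate DNM and PZM filtering.

A de novo mutation on a parental-assembly reference looks like a
homozygous-ALT genotype in the offspring on the inherited contig (only
reads from that haplotype map there) with the site absent from both
parents.  The seven DNM criteria are conjunctive: callable-set membership,
genotype/depth, parental allele count, caller-scoped QUAL, INDEL proximity,
gene-conversion mask, and absence of heterozygous carriers among the other
offspring.  Postzygotic mutations relax the genotype requirement
(heterozygous candidates are kept), exclude unphased regions entirely, and
add a variant-allele-fraction test against the 0.25 expected for a
mutation arising at the first postzygotic division or later.

Because coordinates live on parental contigs, the parental origin of a
mutation is simply the parent of origin of its contig; no read-backed
phasing is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .callable_genome import CallableSet
from .core_io import (
    CALLER_PILEUP,
    ConversionMask,
    DepthTrack,
    VariantObservation,
)

ORIGIN_UNPHASED = "unphased"

DEFAULT_QUAL_MIN = 220.0
DEFAULT_OFFSPRING_DP_MIN = 10
DEFAULT_PARENT_DP_MIN = 5
DEFAULT_INDEL_FLANK = 20
DEFAULT_VAF_NULL = 0.25
DEFAULT_VAF_ALPHA = 0.05
MAX_PARENT_ALT_ALLELES = 2
CLUSTER_CAP_PER_CONTIG = 2


@dataclass
class DnmRecord:
    offspring_id: str
    contig_id: str
    pos: int
    ref_base: str
    alt_base: str
    origin: str
    substitution_class: Optional[str] = None
    shared_group_id: Optional[str] = None
    context: str = "unannotated"
    review_flag: bool = False


@dataclass
class PzmRecord(DnmRecord):
    alt_depth: int = 0
    total_depth: int = 0
    vaf: float = 0.0
    p_value_vs_quarter: float = 1.0


@dataclass
class FilterLog:
    """First failing criterion per rejected site."""

    rejected: list[tuple[str, int, str]] = field(default_factory=list)
    n_missing_partner: int = 0

    def add(self, contig: str, pos: int, reason: str) -> None:
        self.rejected.append((contig, pos, reason))


def merge_caller_calls(
    pileup_calls: Iterable[VariantObservation],
    haplotype_calls: Iterable[VariantObservation],
    high_similarity_contigs: Iterable[str],
) -> list[VariantObservation]:
    """Combine the two callers' call sets.

    On contigs with high cross-parent sequence similarity only the
    haplotype-aware caller is trusted; elsewhere the union of both callers
    is kept (a site called twice yields two tagged observations).
    """
    high = set(high_similarity_contigs)
    merged = [o for o in pileup_calls if o.contig_id not in high]
    merged.extend(haplotype_calls)
    return merged


def indel_positions_from(observations: Iterable[VariantObservation]) -> set[tuple[str, int]]:
    return {(o.contig_id, o.pos) for o in observations if o.is_indel}


def _parent_alt_allele_count(call, n_alts: int) -> Optional[int]:
    """Number of distinct ALT alleles with read support in a parent sample."""
    if call is None or call.allele_depths is None:
        return None
    ads = call.allele_depths[1 : n_alts + 1]
    return sum(1 for d in ads if d > 0)


def _offspring_alt(obs: VariantObservation, gt: tuple[int, int]) -> Optional[str]:
    idx = max(gt)
    if idx < 1 or idx > len(obs.alt_alleles):
        return None
    return obs.alt_alleles[idx - 1]


def dnm_filter(
    trio_observations: Sequence[VariantObservation],
    callable_set_: CallableSet,
    all_offspring_genotypes: Mapping[tuple[str, int], Mapping[str, tuple[int, int]]],
    indel_positions: set[tuple[str, int]],
    conversion_mask: ConversionMask,
    offspring_id: str,
    mother_id: str,
    father_id: str,
    contig_parents: Mapping[str, str],
    qual_min: float = DEFAULT_QUAL_MIN,
    offspring_dp_min: int = DEFAULT_OFFSPRING_DP_MIN,
    parent_dp_min: int = DEFAULT_PARENT_DP_MIN,
    indel_flank: int = DEFAULT_INDEL_FLANK,
    log: Optional[FilterLog] = None,
) -> list[DnmRecord]:
    """Apply the conjunctive DNM criteria to one offspring's merged calls.

    Only single-nucleotide sites are considered.  A site passes if any of
    its (possibly multi-caller) observations passes; the QUAL threshold
    applies to the pileup caller only.  Candidates clustered beyond
    ``CLUSTER_CAP_PER_CONTIG`` per contig are flagged for review rather than
    silently kept.
    """
    log = log if log is not None else FilterLog()
    indels_by_contig: dict[str, np.ndarray] = {}
    for c, p in indel_positions:
        indels_by_contig.setdefault(c, []).append(p)  # type: ignore[arg-type]
    indels_by_contig = {c: np.asarray(sorted(v)) for c, v in indels_by_contig.items()}

    passed: dict[tuple[str, int, str], DnmRecord] = {}
    for obs in trio_observations:
        if obs.contig_id not in contig_parents:
            raise KeyError(f"observation on contig {obs.contig_id} absent from the contig table")
        if not obs.is_snv:
            continue
        site = (obs.contig_id, obs.pos)
        # (i) inside the callable set
        if not callable_set_.contains(*site):
            log.add(*site, "outside_callable")
            continue
        # (ii) offspring hom-ALT with depth, inherited parent covered
        ocall = obs.samples.get(offspring_id)
        if ocall is None or not ocall.is_hom_alt():
            log.add(*site, "not_hom_alt")
            continue
        alt = _offspring_alt(obs, ocall.genotype)
        if alt is None or len(alt) != 1:
            log.add(*site, "bad_alt")
            continue
        if ocall.total_depth is None or ocall.total_depth <= offspring_dp_min:
            log.add(*site, "offspring_depth")
            continue
        origin = contig_parents[obs.contig_id]
        parent_id = mother_id if origin == "maternal" else father_id
        pcall = obs.samples.get(parent_id)
        if pcall is None or pcall.total_depth is None or pcall.total_depth <= parent_dp_min:
            log.add(*site, "parent_depth")
            continue
        # (iii) at most two ALT alleles with support in each parent
        reject = False
        for pid in (mother_id, father_id):
            n_alt = _parent_alt_allele_count(obs.samples.get(pid), len(obs.alt_alleles))
            if n_alt is not None and n_alt > MAX_PARENT_ALT_ALLELES:
                reject = True
        if reject:
            log.add(*site, "parent_alt_alleles")
            continue
        # (iv) QUAL, pileup caller only
        if obs.caller == CALLER_PILEUP and obs.qual < qual_min:
            log.add(*site, "qual")
            continue
        # (v) INDEL proximity (distance <= flank rejects)
        near = indels_by_contig.get(obs.contig_id)
        if near is not None and near.size:
            i = np.searchsorted(near, obs.pos)
            dists = []
            if i < near.size:
                dists.append(abs(int(near[i]) - obs.pos))
            if i > 0:
                dists.append(abs(int(near[i - 1]) - obs.pos))
            if dists and min(dists) <= indel_flank:
                log.add(*site, "near_indel")
                continue
        # (vi) gene-conversion mask
        if site in conversion_mask:
            log.add(*site, "conversion_mask")
            continue
        # (vii) no other offspring heterozygous at this contig site
        carriers = all_offspring_genotypes.get(site, {})
        het_other = any(
            oid != offspring_id and gt is not None and gt[0] != gt[1]
            for oid, gt in carriers.items()
        )
        if het_other:
            log.add(*site, "het_in_other_offspring")
            continue
        rec = DnmRecord(
            offspring_id=offspring_id,
            contig_id=obs.contig_id,
            pos=obs.pos,
            ref_base=obs.ref_allele,
            alt_base=alt,
            origin=ORIGIN_UNPHASED if callable_set_.is_unphased(obs.contig_id) else origin,
        )
        passed.setdefault((obs.contig_id, obs.pos, alt), rec)

    records = sorted(passed.values(), key=lambda r: (r.contig_id, r.pos))
    per_contig: dict[str, int] = {}
    for r in records:
        per_contig[r.contig_id] = per_contig.get(r.contig_id, 0) + 1
    for r in records:
        if per_contig[r.contig_id] > CLUSTER_CAP_PER_CONTIG:
            r.review_flag = True
    return records


def group_shared_dnms(dnm_records: Sequence[DnmRecord]) -> list[DnmRecord]:
    """Assign a shared-group id to identical mutations found in >= 2 siblings.

    Sibling-shared DNMs (ssDNMs) arise before or during early primordial
    germ cell proliferation; each sharing offspring keeps its own record.
    """
    by_site: dict[tuple[str, int, str], list[DnmRecord]] = {}
    for r in dnm_records:
        by_site.setdefault((r.contig_id, r.pos, r.alt_base), []).append(r)
    out: list[DnmRecord] = []
    group_no = 0
    for key in sorted(by_site):
        recs = by_site[key]
        offspring = {r.offspring_id for r in recs}
        gid = None
        if len(offspring) >= 2:
            group_no += 1
            gid = f"ssg{group_no}"
        for r in recs:
            out.append(replace(r, shared_group_id=gid))
    return out


def vaf_test(alt_depth: int, total_depth: int, null_fraction: float = DEFAULT_VAF_NULL) -> float:
    """One-sided test of proportion > ``null_fraction``.

    Chi-square score statistic with continuity correction, halved to one
    tail (the behaviour of R's ``prop.test(..., alternative="greater")``).
    Retention means p > 0.05: the VAF is NOT significantly above the null.
    """
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    if not (0 <= alt_depth <= total_depth):
        raise ValueError("alt_depth out of range")
    n = total_depth
    p0 = null_fraction
    phat = alt_depth / n
    correction = min(0.5 / n, abs(phat - p0))
    z = (phat - p0 - np.sign(phat - p0) * correction) / np.sqrt(p0 * (1 - p0) / n)
    return float(stats.norm.sf(z))


def pzm_filter(
    trio_observations: Sequence[VariantObservation],
    callable_set_: CallableSet,
    all_offspring_genotypes: Mapping[tuple[str, int], Mapping[str, tuple[int, int]]],
    other_sample_alt_depths: Mapping[tuple[str, int], Mapping[str, int]],
    conversion_mask: ConversionMask,
    indel_positions: set[tuple[str, int]],
    offspring_id: str,
    mother_id: str,
    father_id: str,
    contig_parents: Mapping[str, str],
    allelic_partners: Mapping[str, str],
    offspring_depth_tracks: Mapping[str, DepthTrack],
    qual_min: float = DEFAULT_QUAL_MIN,
    offspring_dp_min: int = DEFAULT_OFFSPRING_DP_MIN,
    parent_dp_min: int = DEFAULT_PARENT_DP_MIN,
    indel_flank: int = DEFAULT_INDEL_FLANK,
    null_fraction: float = DEFAULT_VAF_NULL,
    alpha: float = DEFAULT_VAF_ALPHA,
    max_carrier_alt_reads: int = 2,
    log: Optional[FilterLog] = None,
) -> list[PzmRecord]:
    """Candidate postzygotic mutations in one offspring.

    Compared with the DNM criteria: unphased regions are excluded entirely,
    heterozygous offspring genotypes are retained, and no other parental or
    offspring sample may carry more than ``max_carrier_alt_reads``
    alternative-allele reads at the position.  The VAF denominator spans
    both allelic contigs (the focal contig plus the other parent's
    inherited counterpart); candidates whose VAF is significantly above
    ``null_fraction`` are dropped.
    """
    log = log if log is not None else FilterLog()
    indels_by_contig: dict[str, np.ndarray] = {}
    for c, p in indel_positions:
        indels_by_contig.setdefault(c, []).append(p)  # type: ignore[arg-type]
    indels_by_contig = {c: np.asarray(sorted(v)) for c, v in indels_by_contig.items()}

    passed: dict[tuple[str, int, str], PzmRecord] = {}
    for obs in trio_observations:
        if not obs.is_snv:
            continue
        site = (obs.contig_id, obs.pos)
        if obs.contig_id not in contig_parents:
            raise KeyError(f"observation on contig {obs.contig_id} absent from the contig table")
        # (i') unphased regions are not PZM-callable
        if callable_set_.is_unphased(obs.contig_id):
            log.add(*site, "unphased_region")
            continue
        if not callable_set_.contains(*site):
            log.add(*site, "outside_callable")
            continue
        # (ii') het or hom-ALT genotypes retained
        ocall = obs.samples.get(offspring_id)
        if ocall is None or ocall.genotype is None or max(ocall.genotype) < 1:
            log.add(*site, "no_alt_genotype")
            continue
        alt = _offspring_alt(obs, ocall.genotype)
        if alt is None or len(alt) != 1:
            log.add(*site, "bad_alt")
            continue
        if ocall.total_depth is None or ocall.total_depth <= offspring_dp_min:
            log.add(*site, "offspring_depth")
            continue
        origin = contig_parents[obs.contig_id]
        parent_id = mother_id if origin == "maternal" else father_id
        pcall = obs.samples.get(parent_id)
        if pcall is None or pcall.total_depth is None or pcall.total_depth <= parent_dp_min:
            log.add(*site, "parent_depth")
            continue
        if obs.caller == CALLER_PILEUP and obs.qual < qual_min:
            log.add(*site, "qual")
            continue
        near = indels_by_contig.get(obs.contig_id)
        if near is not None and near.size:
            i = np.searchsorted(near, obs.pos)
            dists = []
            if i < near.size:
                dists.append(abs(int(near[i]) - obs.pos))
            if i > 0:
                dists.append(abs(int(near[i - 1]) - obs.pos))
            if dists and min(dists) <= indel_flank:
                log.add(*site, "near_indel")
                continue
        if site in conversion_mask:
            log.add(*site, "conversion_mask")
            continue
        # (iii') no other sample with > max_carrier_alt_reads ALT reads
        alt_idx = max(ocall.genotype)
        carrier = False
        for pid in (mother_id, father_id):
            pc = obs.samples.get(pid)
            if pc is not None and pc.allele_depths is not None and len(pc.allele_depths) > alt_idx:
                if pc.allele_depths[alt_idx] > max_carrier_alt_reads:
                    carrier = True
        for sid, depth in other_sample_alt_depths.get(site, {}).items():
            if sid != offspring_id and depth > max_carrier_alt_reads:
                carrier = True
        if carrier:
            log.add(*site, "alt_reads_in_other_sample")
            continue
        # VAF over both allelic contigs
        partner = allelic_partners.get(obs.contig_id)
        if partner is None:
            log.n_missing_partner += 1
            warnings.warn(
                f"{offspring_id}: no allelic counterpart for {obs.contig_id}; "
                "PZM candidate dropped",
                stacklevel=2,
            )
            continue
        if ocall.allele_depths is None or len(ocall.allele_depths) <= alt_idx:
            log.add(*site, "missing_ad")
            continue
        alt_depth = int(ocall.allele_depths[alt_idx])
        partner_track = offspring_depth_tracks.get(partner)
        if partner_track is None:
            log.n_missing_partner += 1
            continue
        rel = min(obs.pos, partner_track.length - 1)
        partner_dp = partner_track.value_at(rel)
        total = int(round(ocall.total_depth + partner_dp))
        if total <= 0 or alt_depth > total:
            log.add(*site, "bad_vaf_depths")
            continue
        p = vaf_test(alt_depth, total, null_fraction)
        if p <= alpha:
            log.add(*site, "vaf_above_quarter")
            continue
        rec = PzmRecord(
            offspring_id=offspring_id,
            contig_id=obs.contig_id,
            pos=obs.pos,
            ref_base=obs.ref_allele,
            alt_base=alt,
            origin=origin,
            alt_depth=alt_depth,
            total_depth=total,
            vaf=alt_depth / total,
            p_value_vs_quarter=p,
        )
        passed.setdefault((obs.contig_id, obs.pos, alt), rec)
    return sorted(passed.values(), key=lambda r: (r.contig_id, r.pos))
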