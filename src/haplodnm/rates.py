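"""Rate estimators and summary statistics.

The genome-wide per-base per-generation mutation rate is

    mu = n_DNM / (L_callable * (1 - FNR))

where ``L_callable`` is the callable genome size summed over offspring (not
doubled: the reconstructed inherited contigs already represent an
approximately diploid genome per offspring) and FNR is the spike-in
false-negative rate, FNR = 1 - n_detected / n_simulated.  The male mutation
bias alpha is the paternal/maternal DNM count ratio, optionally normalised
by parent-specific callable sizes, and the long-term effective population
size follows from neutral diversity as Ne = pi / (4 mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PafRecord
from .variant_filter import DnmRecord

FOLDED_CLASSES = ("A>C", "A>T", "A>G", "C>A", "C>G", "C>T", "CpG>TpG")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class RateEstimate:
    n_dnm: int
    callable_sum_bp: int
    fnr: float
    mu: float
    ci_low: float
    ci_high: float
    ci_method: str = "poisson_exact"


@dataclass
class AlphaEstimate:
    n_paternal: int
    n_maternal: int
    alpha_raw: float
    alpha_corrected: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    paternal_callable_bp: Optional[int] = None
    maternal_callable_bp: Optional[int] = None


@dataclass
class NeEstimate:
    pi: float
    mu: float
    ne: float


def false_negative_rate(n_detected: int, n_simulated: int) -> float:
    """FNR = 1 - detected/simulated, from a spike-in experiment."""
    if n_simulated <= 0:
        raise ValueError("n_simulated must be positive")
    if not (0 <= n_detected <= n_simulated):
        raise ValueError("need 0 <= n_detected <= n_simulated")
    return 1.0 - n_detected / n_simulated


def _poisson_ci(n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval on a count."""
    alpha = 1.0 - conf
    low = 0.0 if n == 0 else stats.chi2.ppf(alpha / 2, 2 * n) / 2.0
    high = stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0
    return low, high


def mutation_rate(
    n_dnm: int,
    callable_sum_bp: float,
    fnr: float,
    ci_method: str = "poisson_exact",
    conf: float = 0.95,
) -> RateEstimate:
    """Point estimate and CI for the per-base per-generation mutation rate.

    The CI is an exact Poisson interval on the DNM count propagated through
    the same (fixed) denominator.
    """
    if callable_sum_bp <= 0:
        raise ValueError("callable_sum_bp must be positive")
    if not (0 <= fnr < 1):
        raise ValueError("fnr must be in [0, 1)")
    if ci_method != "poisson_exact":
        raise ValueError(f"unknown ci_method: {ci_method}")
    denom = callable_sum_bp * (1.0 - fnr)
    mu = n_dnm / denom
    lo, hi = _poisson_ci(n_dnm, conf)
    return RateEstimate(
        n_dnm=n_dnm,
        callable_sum_bp=int(callable_sum_bp),
        fnr=fnr,
        mu=mu,
        ci_low=lo / denom,
        ci_high=hi / denom,
        ci_method=ci_method,
    )


def alpha_estimate(
    dnm_records: Sequence[DnmRecord] | None = None,
    per_parent_callable_bp: Optional[Mapping[str, float]] = None,
    n_paternal: Optional[int] = None,
    n_maternal: Optional[int] = None,
    conf: float = 0.95,
) -> AlphaEstimate:
    """Male mutation bias from phased DNM counts.

    ``alpha_raw`` = paternal/maternal count ratio; ``alpha_corrected``
    additionally normalises each count by the parent-specific callable size
    (only computed when sizes are supplied).  The CI is a Clopper-Pearson
    interval on the paternal fraction mapped to the alpha scale.  Unphased
    records are excluded.
    """
    if dnm_records is not None:
        n_paternal = sum(1 for r in dnm_records if r.origin == "paternal")
        n_maternal = sum(1 for r in dnm_records if r.origin == "maternal")
    if n_paternal is None or n_maternal is None:
        raise ValueError("need records or explicit counts")
    if n_maternal == 0:
        return AlphaEstimate(n_paternal, n_maternal, float("nan"), None, None, None)
    raw = n_paternal / n_maternal
    lp = lm = None
    corrected = None
    scale = 1.0
    if per_parent_callable_bp is not None:
        lp = int(per_parent_callable_bp["paternal"])
        lm = int(per_parent_callable_bp["maternal"])
        corrected = (n_paternal / lp) / (n_maternal / lm)
        scale = lm / lp
    n = n_paternal + n_maternal
    ci = stats.binomtest(n_paternal, n).proportion_ci(confidence_level=conf, method="exact")
    to_alpha = lambda f: scale * f / (1.0 - f) if f < 1.0 else float("inf")
    return AlphaEstimate(
        n_paternal=n_paternal,
        n_maternal=n_maternal,
        alpha_raw=raw,
        alpha_corrected=corrected,
        ci_low=to_alpha(ci.low),
        ci_high=to_alpha(ci.high),
        paternal_callable_bp=lp,
        maternal_callable_bp=lm,
    )


def substitution_class(ref: str, alt: str, left_base: Optional[str], right_base: Optional[str]) -> str:
    """Folded substitution class with the CpG>TpG transition split out.

    Classes are folded onto an A- or C- reference (e.g. T>G is reported as
    A>C); a C>T whose right-hand neighbour is G -- equivalently a G>A with a
    C on the left -- is the CpG>TpG class.
    """
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base: {b}")
    left = left_base.upper() if left_base else None
    right = right_base.upper() if right_base else None
    if ref in ("T", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        left, right = (
            _COMPLEMENT.get(right) if right else None,
            _COMPLEMENT.get(left) if left else None,
        )
    if ref == "C" and alt == "T" and right == "G":
        return "CpG>TpG"
    return f"{ref}>{alt}"


def classify_dnm_records(
    records: Sequence[DnmRecord],
    contig_sequences: Mapping[str, str],
) -> None:
    """Fill ``substitution_class`` in place from contig sequence context."""
    for r in records:
        seq = contig_sequences.get(r.contig_id)
        if seq is None:
            continue
        left = seq[r.pos - 1] if r.pos > 0 else None
        right = seq[r.pos + 1] if r.pos + 1 < len(seq) else None
        r.substitution_class = substitution_class(r.ref_base, r.alt_base, left, right)


def mutation_spectrum(records: Sequence[DnmRecord]) -> pd.DataFrame:
    """Counts and proportions over the 7 folded substitution classes."""
    counts = {c: 0 for c in FOLDED_CLASSES}
    for r in records:
        if r.substitution_class is None:
            raise ValueError(f"record at {r.contig_id}:{r.pos} lacks a substitution class")
        counts[r.substitution_class] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "class": list(FOLDED_CLASSES),
            "count": [counts[c] for c in FOLDED_CLASSES],
            "proportion": [counts[c] / total if total else 0.0 for c in FOLDED_CLASSES],
        }
    )


def project_annotation(
    contig_to_reference_paf: Sequence[PafRecord],
    reference_context_intervals: Mapping[str, Sequence[tuple[int, int, str]]],
) -> dict[str, list[tuple[int, int, str]]]:
    """Transfer reference annotation contexts onto contig coordinates.

    Each (primary, unique) PAF alignment block maps contig positions
    linearly onto the reference; reference context intervals (exonic /
    intronic / intergenic, non-overlapping) are pulled back through that
    map.  Contig spans without an alignment stay ``unannotated``.
    """
    for ref_name, ivs in reference_context_intervals.items():
        ordered = sorted(ivs)
        for (s1, e1, _), (s2, _, _) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping context intervals on {ref_name}")

    out: dict[str, list[tuple[int, int, str]]] = {}
    for rec in contig_to_reference_paf:
        contexts = sorted(reference_context_intervals.get(rec.tname, []))
        segments = out.setdefault(rec.qname, [])
        for ts, te, label in contexts:
            lo = max(ts, rec.tstart)
            hi = min(te, rec.tend)
            if lo >= hi:
                continue
            if rec.strand == "+":
                qs = rec.qstart + (lo - rec.tstart)
                qe = rec.qstart + (hi - rec.tstart)
            else:
                qs = rec.qstart + (rec.tend - hi)
                qe = rec.qstart + (rec.tend - lo)
            segments.append((qs, qe, label))
    for cid in out:
        out[cid].sort()
    return out


def context_of(contig_id: str, pos: int, context_map: Mapping[str, Sequence[tuple[int, int, str]]]) -> str:
    for s, e, label in context_map.get(contig_id, ()):
        if s <= pos < e:
            return label
    return "unannotated"


def context_rates(
    dnm_records: Sequence[DnmRecord],
    callable_bp_by_context: Mapping[str, float],
    fnr: float,
) -> pd.DataFrame:
    """Per-context mutation rates plus a chi-square homogeneity test.

    The rate in a context is its DNM count over its callable size corrected
    by the global FNR; the test compares observed counts with those expected
    if the rate were uniform across contexts.
    """
    contexts = sorted(callable_bp_by_context)
    counts = {c: 0 for c in contexts}
    for r in dnm_records:
        if r.context in counts:
            counts[r.context] += 1
    rows = []
    for c in contexts:
        bp = callable_bp_by_context[c]
        rate = counts[c] / (bp * (1 - fnr)) if bp > 0 else float("nan")
        rows.append({"context": c, "n_dnm": counts[c], "callable_bp": bp, "rate": rate})
    df = pd.DataFrame(rows)
    observed = df["n_dnm"].to_numpy(dtype=float)
    weights = df["callable_bp"].to_numpy(dtype=float)
    if observed.sum() > 0 and weights.sum() > 0 and len(df) > 1:
        expected = observed.sum() * weights / weights.sum()
        keep = expected > 0
        chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        dof = int(keep.sum()) - 1
        p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    else:
        chi2, p = float("nan"), float("nan")
    df.attrs["chi2"] = chi2
    df.attrs["p_value"] = p
    return df


def effective_population_size(pi: float, mu: float) -> NeEstimate:
    """Long-term effective population size, Ne = pi / (4 mu)."""
    if pi <= 0 or mu <= 0:
        raise ValueError("pi and mu must be positive")
    return NeEstimate(pi=pi, mu=mu, ne=pi / (4.0 * mu))


def origin_contrast(count_table_2x2: Iterable[Iterable[int]]) -> tuple[float, float]:
    """Fisher's exact test (two-sided) on a 2x2 origin-contrast table.

    Returns (odds_ratio, p).  A zero margin yields p = 1 by convention with
    an undefined (nan) odds ratio.
    """
    table = np.asarray([list(row) for row in count_table_2x2], dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
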