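"""Plain-text TSV/BED artifacts handed between pipeline stages.

Every intermediate is inspectable and diffable; numeric thresholds travel
in commented metadata lines so a run is reproducible from its outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .callable_genome import CallableSet
from .contig_classify import ZygosityCall
from .core_io import ContigRecord
from .inheritance import InheritanceCall
from .variant_filter import DnmRecord, PzmRecord


def write_contig_table(path: str | Path, contigs: Sequence[ContigRecord]) -> None:
    rows = [
        {
            "contig_id": c.contig_id,
            "parent": c.parent_of_origin,
            "assembler_class": c.assembler_class,
            "partner_id": c.partner_id or ".",
            "length_bp": c.length_bp,
        }
        for c in contigs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contig_table(path: str | Path, sequences: Optional[Mapping[str, str]] = None) -> list[ContigRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"partner_id": str})
    out = []
    for row in df.itertuples(index=False):
        partner = None if row.partner_id in (".", "", None) else row.partner_id
        seq = sequences.get(row.contig_id) if sequences else None
        out.append(
            ContigRecord(
                row.contig_id, row.parent, row.assembler_class,
                int(row.length_bp), partner_id=partner, sequence=seq,
            )
        )
    return out


def write_zygosity_table(path: str | Path, calls: Sequence[ZygosityCall]) -> None:
    rows = [
        {
            "contig_id": z.contig_id,
            "category": z.category,
            "mean_depth": round(z.mean_depth, 3),
            "rbh_partner": z.rbh_partner or ".",
            "rbh_coverage": "." if z.rbh_coverage is None else round(z.rbh_coverage, 4),
            "rbh_identity": "." if z.rbh_identity is None else round(z.rbh_identity, 4),
        }
        for z in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_zygosity_table(path: str | Path) -> dict[str, ZygosityCall]:
    df = pd.read_csv(path, sep="\t", dtype={"rbh_partner": str})
    out = {}
    for row in df.itertuples(index=False):
        out[row.contig_id] = ZygosityCall(
            contig_id=row.contig_id,
            category=row.category,
            mean_depth=float(row.mean_depth),
            rbh_partner=None if row.rbh_partner in (".", "", None) else row.rbh_partner,
            rbh_coverage=None if row.rbh_coverage == "." else float(row.rbh_coverage),
            rbh_identity=None if row.rbh_identity == "." else float(row.rbh_identity),
        )
    return out


def write_inheritance_table(
    path: str | Path,
    calls: Mapping[str, InheritanceCall],
    parental_scores: Mapping[str, float],
) -> None:
    rows = []
    for cid, c in sorted(calls.items()):
        rows.append(
            {
                "offspring_id": c.offspring_id,
                "contig_id": cid,
                "state": c.state,
                "stage": c.stage,
                "basis": c.basis,
                "similarity_to_origin": _fmt(c.similarity_to_origin),
                "similarity_to_other": _fmt(c.similarity_to_other),
                "parental_similarity": _fmt(parental_scores.get(cid)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_inheritance_table(path: str | Path) -> tuple[dict[str, InheritanceCall], dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    calls, scores = {}, {}
    for row in df.itertuples(index=False):
        calls[row.contig_id] = InheritanceCall(
            offspring_id=row.offspring_id,
            contig_id=row.contig_id,
            state=row.state,
            stage=int(row.stage),
            basis=row.basis,
            similarity_to_origin=_unfmt(row.similarity_to_origin),
            similarity_to_other=_unfmt(row.similarity_to_other),
        )
        score = _unfmt(row.parental_similarity)
        if score is not None:
            scores[row.contig_id] = score
    return calls, scores


def write_callable(bed_path: str | Path, summary_path: str | Path, cset: CallableSet) -> None:
    with open(bed_path, "w") as fh:
        for phase, ivmap in (("phased", cset.phased_intervals), ("unphased", cset.unphased_intervals)):
            for cid in sorted(ivmap):
                for s, e in ivmap[cid]:
                    fh.write(f"{cid}\t{s}\t{e}\t{phase}\n")
    pd.DataFrame(
        [
            {
                "offspring_id": cset.offspring_id,
                "total_bp": cset.total_bp,
                "phased_bp": cset.phased_bp,
                "unphased_bp_contribution": cset.unphased_bp_contribution,
                "n_contigs": len(cset.phased_intervals) + len(cset.unphased_intervals),
            }
        ]
    ).to_csv(summary_path, sep="\t", index=False)


def read_callable(
    bed_path: str | Path,
    offspring_id: str,
    contig_lengths: Mapping[str, int],
) -> CallableSet:
    cset = CallableSet(offspring_id)
    with open(bed_path) as fh:
        for line in fh:
            cid, s, e, phase = line.rstrip("\n").split("\t")[:4]
            target = cset.phased_intervals if phase == "phased" else cset.unphased_intervals
            target.setdefault(cid, []).append((int(s), int(e)))
            if phase == "unphased":
                cset.unphased_contig_lengths[cid] = int(contig_lengths[cid])
    return cset


def write_mutation_table(path: str | Path, records: Sequence[DnmRecord]) -> None:
    rows = []
    for r in records:
        row = {
            "offspring_id": r.offspring_id,
            "contig_id": r.contig_id,
            "pos": r.pos,
            "ref": r.ref_base,
            "alt": r.alt_base,
            "origin": r.origin,
            "substitution_class": r.substitution_class or ".",
            "shared_group_id": r.shared_group_id or ".",
            "context": r.context,
            "review_flag": int(r.review_flag),
        }
        if isinstance(r, PzmRecord):
            row.update(
                alt_depth=r.alt_depth,
                total_depth=r.total_depth,
                vaf=round(r.vaf, 4),
                p_value_vs_quarter=f"{r.p_value_vs_quarter:.4g}",
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x: Optional[float]) -> str:
    return "." if x is None else f"{x:.4f}"


def _unfmt(x) -> Optional[float]:
    if x is None or (isinstance(x, str) and x == "."):
        return None
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return None if pd.isna(v) else v
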