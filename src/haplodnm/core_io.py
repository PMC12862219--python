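"""Shared domain types and readers/writers for the standard formats.

Coordinate convention: everything in memory is 0-based, half-open.  VCF is
the only 1-based surface; positions are shifted on read (``pos - 1``) and on
write (``pos + 1``).

Depth tracks are stored run-length encoded (mosdepth-style per-base BED
intervals) and expanded lazily: both the 50-bp binning used by inheritance
inference and the interval filters used by the callable-genome stage operate
naturally on runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

MIN_CONTIG_LENGTH = 150

MATERNAL = "maternal"
PATERNAL = "paternal"

BUBBLE_PRIMARY = "bubble_primary"
BUBBLE_SECONDARY = "bubble_secondary"
NON_BUBBLE = "non_bubble"

CALLER_PILEUP = "caller_pileup"
CALLER_HAPLOTYPE = "caller_haplotype"


@dataclass
class ContigRecord:
    """One contig of a parental allele-aware assembly.

    ``assembler_class`` reflects what the assembler emitted: bubble contigs
    (primary/secondary allelic pair) or non-bubble contigs, which in practice
    are a mixture of homozygous and unresolved heterozygous sequence.
    """

    contig_id: str
    parent_of_origin: str
    assembler_class: str
    length_bp: int
    partner_id: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.parent_of_origin not in (MATERNAL, PATERNAL):
            raise ValueError(f"bad parent_of_origin: {self.parent_of_origin}")
        if self.assembler_class not in (BUBBLE_PRIMARY, BUBBLE_SECONDARY, NON_BUBBLE):
            raise ValueError(f"bad assembler_class: {self.assembler_class}")
        if self.length_bp < MIN_CONTIG_LENGTH:
            raise ValueError(
                f"{self.contig_id}: contigs shorter than {MIN_CONTIG_LENGTH} bp "
                "are filtered from the assembly"
            )
        if self.assembler_class in (BUBBLE_PRIMARY, BUBBLE_SECONDARY) and not self.partner_id:
            raise ValueError(f"{self.contig_id}: bubble contig without partner_id")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(f"{self.contig_id}: sequence length != length_bp")


@dataclass(frozen=True)
class PafRecord:
    """Standard minimap2 PAF columns 1-12 (0-based half-open coordinates)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query interval in PAF record {self.qname}->{self.tname}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target interval in PAF record {self.qname}->{self.tname}")
        if self.n_matches > self.block_len:
            raise ValueError(f"n_matches > block_len in PAF record {self.qname}->{self.tname}")


class DepthTrack:
    """Run-length encoded per-base read depth of one individual on one contig.

    ``starts``/``ends``/``values`` are parallel arrays of intervals that must
    tile ``[0, length)`` without gaps or overlaps.
    """

    __slots__ = ("contig_id", "individual_id", "starts", "ends", "values")

    def __init__(
        self,
        contig_id: str,
        individual_id: str,
        starts: Sequence[int],
        ends: Sequence[int],
        values: Sequence[float],
    ) -> None:
        self.contig_id = contig_id
        self.individual_id = individual_id
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.values = np.asarray(values, dtype=np.float64)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError(f"{contig_id}: ragged run-length arrays")
        if len(self.starts) == 0:
            raise ValueError(f"{contig_id}: empty depth track")
        if self.starts[0] != 0:
            raise ValueError(f"{contig_id}: depth intervals do not start at 0")
        if np.any(self.ends <= self.starts):
            raise ValueError(f"{contig_id}: empty or inverted depth interval")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError(f"{contig_id}: gap or overlap in depth interval tiling")
        if np.any(self.values < 0):
            raise ValueError(f"{contig_id}: negative depth")

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    @classmethod
    def from_array(cls, contig_id: str, individual_id: str, per_base: Sequence[float]) -> "DepthTrack":
        arr = np.asarray(per_base, dtype=np.float64)
        if arr.size == 0:
            raise ValueError(f"{contig_id}: zero-length depth array")
        change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        return cls(contig_id, individual_id, starts, ends, arr[starts])

    def to_array(self) -> np.ndarray:
        return np.repeat(self.values, self.ends - self.starts)

    def mean(self) -> float:
        """Arithmetic mean of per-base depth across the contig length."""
        lengths = self.ends - self.starts
        return float(np.dot(self.values, lengths) / lengths.sum())

    def value_at(self, pos: int) -> float:
        """Depth at a single 0-based position."""
        if not (0 <= pos < self.length):
            raise IndexError(f"{self.contig_id}: position {pos} out of range")
        i = int(np.searchsorted(self.ends, pos, side="right"))
        return float(self.values[i])

    def high_depth_intervals(self, threshold: float) -> list[tuple[int, int]]:
        """0-based half-open intervals where depth strictly exceeds threshold."""
        out: list[tuple[int, int]] = []
        for s, e, v in zip(self.starts, self.ends, self.values):
            if v > threshold:
                if out and out[-1][1] == s:
                    out[-1] = (out[-1][0], int(e))
                else:
                    out.append((int(s), int(e)))
        return out


@dataclass(frozen=True)
class SampleCall:
    """Per-sample FORMAT fields of one VCF record."""

    genotype: Optional[tuple[int, int]]
    total_depth: Optional[int]
    allele_depths: Optional[tuple[int, ...]]

    def is_hom_alt(self) -> bool:
        gt = self.genotype
        return gt is not None and gt[0] == gt[1] and gt[0] > 0

    def is_het(self) -> bool:
        gt = self.genotype
        return gt is not None and gt[0] != gt[1]


@dataclass
class VariantObservation:
    """One VCF site as seen by one caller; ``pos`` is 0-based internally."""

    contig_id: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    caller: str
    samples: dict[str, SampleCall] = field(default_factory=dict)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != 1 or any(len(a) != 1 for a in self.alt_alleles)


class ConversionMask:
    """Set of (contig_id, pos) sites flagged as putative gene conversions.

    Gene conversions produce read alignments that mimic de novo mutations;
    masked sites are excluded from the DNM candidate set.
    """

    def __init__(self, sites: Iterable[tuple[str, int]] = ()) -> None:
        self._sites = frozenset((str(c), int(p)) for c, p in sites)

    def __contains__(self, site: tuple[str, int]) -> bool:
        return (site[0], int(site[1])) in self._sites

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites)

    @classmethod
    def read(cls, path: str | Path) -> "ConversionMask":
        sites = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                contig, pos = line.split("\t")[:2]
                sites.append((contig, int(pos)))
        return cls(sites)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, pos in sorted(self._sites):
                fh.write(f"{contig}\t{pos}\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{contig_id: uppercased sequence}``.

    Duplicate IDs are a hard error; an empty file returns an empty mapping
    with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA ID: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return out


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 80) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_paf(path: str | Path, min_mapq: int = 0) -> list[PafRecord]:
    """Parse a 12+ column PAF file, dropping records with mapq < min_mapq."""
    out: list[PafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}: malformed PAF line {lineno} ({len(cols)} columns)")
            try:
                rec = PafRecord(
                    qname=cols[0], qlen=int(cols[1]), qstart=int(cols[2]), qend=int(cols[3]),
                    strand=cols[4],
                    tname=cols[5], tlen=int(cols[6]), tstart=int(cols[7]), tend=int(cols[8]),
                    n_matches=int(cols[9]), block_len=int(cols[10]), mapq=int(cols[11]),
                )
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: malformed PAF line {lineno}: {err}") from err
            if rec.mapq >= min_mapq:
                out.append(rec)
    return out


def write_paf(path: str | Path, records: Iterable[PafRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.qname}\t{r.qlen}\t{r.qstart}\t{r.qend}\t{r.strand}\t"
                f"{r.tname}\t{r.tlen}\t{r.tstart}\t{r.tend}\t"
                f"{r.n_matches}\t{r.block_len}\t{r.mapq}\n"
            )


def read_depth_bed(path: str | Path, individual_id: Optional[str] = None) -> list[DepthTrack]:
    """Read a mosdepth-style per-base BED (contig, start, end, depth).

    Intervals per contig must be sorted, non-overlapping and tile the contig
    from 0; a gap or overlap raises an error naming the contig.
    """
    if individual_id is None:
        individual_id = Path(path).name.split(".")[0]
    per_contig: dict[str, list[tuple[int, int, float]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end, depth = line.split("\t")[:4]
            if contig not in per_contig:
                per_contig[contig] = []
                order.append(contig)
            per_contig[contig].append((int(start), int(end), float(depth)))
    tracks = []
    for contig in order:
        rows = per_contig[contig]
        starts, ends, values = zip(*rows)
        tracks.append(DepthTrack(contig, individual_id, starts, ends, values))
    return tracks


def write_depth_bed(path: str | Path, tracks: Iterable[DepthTrack]) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for s, e, v in zip(t.starts, t.ends, t.values):
                val = int(v) if float(v).is_integer() else v
                fh.write(f"{t.contig_id}\t{s}\t{e}\t{val}\n")


def _parse_gt(gt_entry) -> Optional[tuple[int, int]]:
    # cyvcf2 genotypes entries are [allele1, allele2, phased]
    a, b = gt_entry[0], gt_entry[1]
    if a < 0 or b < 0:
        return None
    return (int(a), int(b))


def read_trio_vcf(path: str | Path, caller_tag: str) -> list[VariantObservation]:
    """Read a VCF 4.x into VariantObservations tagged with ``caller_tag``.

    Multi-allelic sites are kept unsplit.  Records missing AD or DP keep the
    field as None; downstream filters reject them.  Positions are converted
    to the internal 0-based convention.
    """
    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    out: list[VariantObservation] = []
    for var in vcf:
        gts = var.genotypes
        try:
            dps = var.format("DP")
        except KeyError:
            dps = None
        try:
            ads = var.format("AD")
        except KeyError:
            ads = None
        samples: dict[str, SampleCall] = {}
        for i, name in enumerate(sample_names):
            dp = None
            if dps is not None and int(dps[i][0]) >= 0:
                dp = int(dps[i][0])
            ad = None
            if ads is not None:
                row = [int(x) for x in ads[i]]
                if all(x >= 0 for x in row):
                    ad = tuple(row)
            samples[name] = SampleCall(
                genotype=_parse_gt(gts[i]) if gts else None,
                total_depth=dp,
                allele_depths=ad,
            )
        out.append(
            VariantObservation(
                contig_id=var.CHROM,
                pos=var.POS - 1,
                ref_allele=var.REF,
                alt_alleles=tuple(var.ALT),
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                caller=caller_tag,
                samples=samples,
            )
        )
    vcf.close()
    return out


def write_trio_vcf(
    path: str | Path,
    observations: Sequence[VariantObservation],
    sample_names: Sequence[str],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write observations as a plain-text VCF 4.2 (1-based on disk)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        key = lambda o: (o.contig_id, o.pos)
        for obs in sorted(observations, key=key):
            fields = [
                obs.contig_id, str(obs.pos + 1), ".", obs.ref_allele,
                ",".join(obs.alt_alleles), f"{obs.qual:g}", ".", ".", "GT:DP:AD",
            ]
            for name in sample_names:
                call = obs.samples.get(name)
                if call is None:
                    fields.append("./.:.:.")
                    continue
                gt = "./." if call.genotype is None else f"{call.genotype[0]}/{call.genotype[1]}"
                dp = "." if call.total_depth is None else str(call.total_depth)
                ad = "." if call.allele_depths is None else ",".join(map(str, call.allele_depths))
                fields.append(f"{gt}:{dp}:{ad}")
            fh.write("\t".join(fields) + "\n")
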