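"""Simulate a small heterozygous diploid pedigree with full truth records.

Two parents at 3% genome-wide heterozygosity are contigized into bubble
pairs (heterozygous alleles) and homozygous contigs, half of the bubble
pairs are mislabeled as assembler "non-bubble" output, and two offspring
receive one haplotype per segment per parent.
"""

from haplodnm import SimConfig, simulate_pedigree

config = SimConfig(
    genome_length_bp=1_000_000,
    n_no_variant_intervals=6,
    no_variant_interval_length_bp=75_000,
    n_offspring=2,
    seed=42,
)
sim = simulate_pedigree(config)

n_het = sum(1 for z in sim.truth.true_zygosity.values() if z == "het")
n_hom = sum(1 for z in sim.truth.true_zygosity.values() if z == "hom")
n_shared = sum(1 for s in sim.truth.segments if s.shared)

print(f"contigs emitted        : {len(sim.contigs)}")
print(f"  heterozygous (truth) : {n_het}")
print(f"  homozygous   (truth) : {n_hom}")
print(f"segments               : {len(sim.truth.segments)} "
      f"({n_shared} with shared parental ancestry)")
print(f"offspring              : {config.offspring_ids}")

# The contig count splits into bubble pairs (two contigs per heterozygous
# segment) plus one contig per homozygous segment; shared-ancestry segments
# are where the parents carry near-identical alleles, which later confound
# inheritance inference and are excluded from the callable genome.
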