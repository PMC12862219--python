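"""Spike DNMs/PZMs into a pedigree, run the filters, and score recovery.

The candidate filters mirror a conservative trio pipeline: callable-set
membership, homozygous-ALT genotype with depth support, parental allele
counts, a caller-scoped QUAL threshold, INDEL proximity, a gene-conversion
mask, and the absence of heterozygous sibling carriers.  Postzygotic
candidates additionally pass a one-sided proportion test of VAF vs 0.25.
"""

from haplodnm import SimConfig
from haplodnm.simulate import run_benchmarks

report = run_benchmarks(SimConfig(
    genome_length_bp=1_000_000, n_no_variant_intervals=6,
    no_variant_interval_length_bp=75_000, n_offspring=3,
    dnm_spike_per_offspring=40, pzm_spike_per_offspring=20, seed=9))

print(f"DNMs spiked (rate set)  : {report.n_dnm_spiked}")
print(f"DNMs detected           : {report.n_dnm_detected}")
print(f"spike-in FNR            : {report.fnr:.3f}")
print(f"PZMs spiked / recovered : {report.n_pzm_spiked} / {report.n_pzm_detected}")
print(f"PZM VAF mean abs error  : {report.pzm_vaf_mae:.3f}")
# The FNR reflects the observation-noise model (low-QUAL calls, caller
# misses); recovered PZM VAFs track the spiked Beta-distributed truth, and
# candidates whose VAF significantly exceeds 0.25 (true germline variants)
# are excluded.
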