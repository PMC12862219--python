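# Methods

This note documents the models, parameter choices and numerical decisions
behind `haplodnm`, in the spirit of a methods supplement: what each stage
assumes, where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Reference model

All coordinates are 0-based half-open internally; VCF is the only 1-based
surface (converted on read/write). The alignment reference is the
concatenation of both parents' allele-aware contig assemblies. Contigs come
in three assembler classes: bubble primary/secondary (an allelic pair from
a heterozygous region) and non-bubble (nominally homozygous, in practice a
mixture). Contigs shorter than 150 bp are excluded by construction. Depth
tracks are run-length encoded; both the 50-bp binning and the interval
filters operate on runs.

## Contig zygosity classification

A parent's reads mapped back to its own assembly cover a single-haplotype
(heterozygous) contig at ~half the diploid sequencing depth and a
homozygous contig at full depth, so the contig-mean-depth histogram is
bimodal. The depth windows are anchored at an 80× calibration —
heterozygous `[10, 50]×`, homozygous `(50, 100]×` — and scaled linearly
with the parent's sequencing depth (`default_thresholds`). When that depth
is not supplied it is estimated as twice the length-weighted median of
contig mean depths: most assembly length is single-haplotype, so the
weighted median sits on the haploid peak.

RBH machinery: alignment blocks between the same two contigs are
aggregated (identity = Σmatches/Σblock length; coverage = merged aligned
span over sequence length, taken as the min of the query- and target-side
values so containment cannot qualify asymmetrically); pairs need ≥ 0.7 on
both metrics; a contig's best hit maximises total matches and a tie
rejects the pair (conservative reading of "reciprocal best"). Identity is
plain matches/block-length (not gap-compressed). Candidate-heterozygous
RBH pairs become bubble-like pairs; candidate-homozygous contigs with
*any* qualifying RBH are demoted to uncertain ("negative list"); the rest
of the depth-window homozygous candidates are true non-bubble. Assembler
bubble contigs are trusted as-is and double as an internal positive
control: pushed through the same pipeline, ≥ ~99% are re-identified as
heterozygous in the default benchmark.

## Inheritance inference

Depth profiles are 50-bp bin means (trailing partial bin dropped). The
similarity of two profiles is

    S = w_nz · cosine(u, v | both > 0)  +  w_z · J_zero ,

where the cosine is over bins with non-zero depth in both individuals,
`J_zero` = (#bins zero in both)/(#bins zero in at least one), and the
weights are the corresponding bin-count proportions. The Jaccard reading —
agreement of the *zero-coverage patterns* — is the single most
consequential interpretation in this module: it makes S equal 1 for
identical uncovered regions and 0 for disjoint coverage, which is exactly
the signal that separates "same allele" from "different allele" when the
non-carrier parent has sparse mismapped coverage. Cosine uses raw bin
means (it is scale-invariant; each vector is normalised by its own maximum
purely to avoid numeric under/overflow).

Stage 1: a contig whose offspring depth is below `max(10, mean/4)` is not
inherited; otherwise it is inherited iff the offspring profile is more
similar to the parent-of-origin's profile than to the other parent's, with
an exact tie left unresolved. The offspring's "mean depth" statistic is
the length-weighted mean over contigs whose raw mean depth is at least the
absolute floor (10×): the unqualified alternative (mean over all contigs
of the combined reference) is dragged down by the ~half of contigs the
offspring did not inherit, and a post-hoc "inherited contigs only" mean
would be circular before stage 1. The same statistic feeds the callable
3× depth cap.

Stage 2 resolves bubble pairs jointly: homozygous (true non-bubble)
contigs are always inherited; if both members' parental similarity scores
exceed 0.5 the pair is unresolvable (both `unresolved`, mutations there
can only be called unphased); a low-depth member forces its partner to be
inherited; otherwise the member with score ≤ 0.5 is trusted, and when both
are trustworthy and stage 1 agrees on both-inherited (or both-not), the
member with the lower score is kept (or force-inherited). Uncertain
non-bubble contigs keep their stage-1 call unless their score exceeds 0.5,
in which case they are excluded downstream. Scenarios not derivable from
these rules map to `unresolved` rather than a guess.

## Callable genome

Starting from inherited contigs: uncertain contigs with score > 0.5 are
dropped; for each highly similar cross-parent allele pair (cross-parent
RBH whose members' parental similarity exceeds 0.5 — the pair score is the
max of the two members', so either confounded member flags the locus),
both-inherited ⇒ both dropped, exactly-one-inherited ⇒ kept unphased at
`floor(length/2)` (bp counts stay integral); high-score contigs without an
identifiable cross-parent homolog are dropped. Then 100 bp is trimmed from
each contig end and positions above 3× the offspring mean depth are
removed (collapsed-repeat proxy). Trimming is applied before the cap; the
result is a set intersection, so the order is immaterial and fixed only
for reproducibility. The unphased half-length contribution deliberately
ignores trims: it is an approximation for loci where exactly one of two
near-identical alleles was inherited.

## Mutation filtering

DNM criteria (conjunctive, order-independent): (i) callable-set
membership; (ii) offspring homozygous-ALT with DP > 10 and the inherited
parent's DP > 5 at the site; (iii) ≤ 2 alternative alleles with read
support in each parent — evaluated from the parental AD fields, the VCF
proxy for per-read alt observations, since this tool ingests VCF rather
than BAM; (iv) QUAL ≥ 220, applied to the pileup-style caller only (the
haplotype-aware caller's scale differs); (v) no INDEL within ±20 bp
(distance > 20 passes — the boundary is exclusive and tested); (vi) not in
the gene-conversion site mask supplied as input (conversion tracts at
parental heterozygous sites are orders of magnitude more likely than DNMs
and mimic them); (vii) no other offspring heterozygous at the same contig
site (heterozygosity implies an inherited variant or mismapping). The
merged call set is scanned for (vii). In regions of high cross-parent
similarity only the haplotype-aware caller's records are used; elsewhere
the union of both callers. Manual review of clustered candidates is
replaced by an automatable proxy: more than 2 candidates on one contig are
flagged `review_flag` (kept, but marked); this proxy does not claim to
reproduce human curation, which removed most of the raw candidates in the
real study.

Sibling-shared DNMs (same contig, position and ALT in ≥ 2 offspring) get a
shared-group id; each sharing offspring contributes its own record to the
counts, consistent with how per-offspring rates are defined.

PZM differences: unphased regions excluded entirely; heterozygous
genotypes retained; no *other* parental or offspring sample may carry > 2
ALT reads at the position; and the VAF — alt reads over the summed depth of
the focal contig and the other parent's inherited allelic contig — must
not be significantly greater than 0.25. The test emulates R's `prop.test`:
a chi-square score statistic with continuity correction, halved to one
tail; it matches `prop.test` to ≥ 5 significant digits on reference values
and agrees with an exact binomial oracle on retention decisions except in
a narrow boundary band (|p − 0.05| < 0.03), which the tests document. The
allelic counterpart for the VAF denominator is the cross-parent contig
(qualifying alignment) that the offspring inherited.

## Estimators

* FNR = 1 − detected/simulated, from spiking known mutations into callable
  regions and re-running the detection chain.
* μ = n_DNM / (L_callable · (1 − FNR)); L_callable is summed over
  offspring and **not** doubled, because each offspring's inherited contig
  set already represents an approximately diploid genome. The 95% CI is an
  exact (Garwood) Poisson interval on the count propagated through the
  fixed denominator; the method name is recorded in outputs. The interval
  construction behind published CIs of this form is rarely stated, so the
  CI endpoints are reported, not asserted against any external value.
* α: raw = paternal/maternal count ratio over phased records; corrected
  divides each count by the parent-specific callable size summed over
  offspring. CI: Clopper–Pearson on the paternal fraction mapped to the α
  scale.
* Spectrum: six folded classes (reference folded to A or C) plus CpG>TpG
  for C>T with a 3′ G (or folded G>A with a 5′ C), from the contig
  sequence context. Proportion error bars use Clopper–Pearson.
* Annotation projection: 12-column PAF blocks define strand-aware linear
  maps from contig to reference coordinates; non-overlapping reference
  context intervals (exonic/intronic/intergenic) are pulled back through
  them; unaligned spans are `unannotated`. Context rates divide per-context
  DNM counts by per-context callable sizes with the global FNR, and a
  chi-square homogeneity test compares contexts.
* N_e = π/(4μ), with π supplied as a scalar (population diversity
  estimation is outside this package's scope).

## Synthetic pedigree generator

The generator replaces read simulation, assembly and alignment with
parametric models of exactly the quantities the pipeline consumes; the
read-level path is the documented extension point it deliberately
abstracts.

* **SNPs**: target count = heterozygosity × genome length, distributed
  over 100-kb windows by independent Poisson draws proportional to window
  weights (uniform by default; a Gamma option mimics empirical SNP-density
  variation without requiring any external variant file), positions
  uniform within windows and excluded from planted no-variant intervals;
  each SNP mutates one random haplotype.
* **Contigization**: both parents share a segment grid (lognormal lengths,
  median 5.5 kb, σ = 0.5, minimum 500 bp — N50 ≈ 7 kb, matching short-read
  allele-aware assemblies); heterozygous segments emit a bubble pair, half
  of which (default 0.5, mirroring the ~56% of non-bubble contigs that
  turn out heterozygous in real assemblies) are emitted as unlabeled
  non-bubble contigs. Mislabeling acts on whole pairs: a failed phasing
  event releases *both* alleles as independent contigs, and a lone
  mislabeled member would have an assembler-bubble partner outside the
  candidate set, making the pairing rule untestable.
* **Shared ancestry**: a fraction (default 0.45) of heterozygous segments
  copy one maternal haplotype into the father, emulating inbred parents;
  reads from such alleles split 50/50 across the two identical contigs.
  No-variant intervals (default 28 × 80 kb on 5 Mb, i.e. 45% of the
  genome) are homozygous in, and identical between, both parents. These
  two fractions were chosen by a closed-form calculation so that the
  per-offspring callable fraction of the diploid genome lands inside the
  34–51% band observed per offspring on real data; they encode how much of
  an inbred pedigree's genome is uninformative for phased mutation
  calling.
* **Depth**: per-50-bp-bin negative binomial (dispersion 10) around
  dose × depth/2, with a per-contig Gamma multiplier (CV 0.1) for
  contig-level coverage variation — the dispersion defaults keep the
  contig-mean histogram clearly bimodal, which classification requires
  (a config warning fires if the contig CV would blur it). Doses: bubble
  member 1 in carriers and 0 otherwise, homozygous contigs 2 in every
  individual. Cross-mapping bleed: a non-carrier allele receives depth in
  a sparse ~5% of bins at carrier intensity — sparse, because mismapped
  coverage is clumpy; uniform bleed would make the (scale-invariant)
  cosine similarity of a non-carrier profile spuriously high.
* **Observations**: trio VCF records are generated at mutation and decoy
  sites only (the reference is the parental assembly, so inherited
  variants are invisible by construction). QUAL ~ N(400, 60) clipped, with
  a 3% low-QUAL fraction and a 1% caller-miss rate — the loss channels
  that give the spike-in FNR its ~4–6% magnitude, deliberately of the
  same order as the 4.8% measured with read-level simulation, though not
  asserted equal since the noise models differ. Decoys exercise each
  rejection path: INDELs within the flank, gene-conversion-mask sites,
  and sites heterozygous in another sibling.
* **Spiking**: DNMs uniform over the offspring's callable set (sibling-
  shared groups of size 2–3 placed on co-inherited contigs; 20% of spikes
  by default, matching the observed ssDNM share); PZMs on phased contigs
  with true VAF ~ Beta(2, 8) (mean 0.2, i.e. post-first-division mosaics)
  and alt reads binomial at twice the VAF on the focal haplotype.

Everything is driven by one seed through named, CRC-derived substreams:
runs are byte-reproducible.

## Benchmarks and their scope

`run_benchmarks` generates a pedigree, runs the full pipeline and scores:
classification accuracy (≥ 95% required; ~99% typical at defaults),
inheritance error over resolved contigs (≤ 3% required; ~0% typical at
defaults — observation-level noise is kinder than real mismapping, so this
is an upper bound on what the logic itself loses, not a claim about real
data), the unresolved fraction (reported separately: an unresolvable locus
is a no-call, not an error), callable fraction, FNR, and μ recovery. The
FNR is estimated from the first offspring's spikes and applied to a rate
computed from the others, mirroring the select-individuals spike-in
strategy.

The CI-calibration study (`mu_recovery_study`, 100 seeded replicates at
μ\* = 10⁻⁶ on a 10-Mb × 30-offspring geometry) runs the estimator chain —
spiking, observation noise, the DNM filter, an independent FNR spike run,
and the Poisson CI — on a fixed callable geometry rather than re-running
assembly classification 100 times; coverage is ~98%, and full end-to-end
inference is exercised separately by `run_benchmarks`. Problem sizes
throughout (1-Mb unit-test pedigrees, 5-Mb benchmark genome) were chosen
as the smallest scales at which every noise channel is populated with
hundreds of events.

What passing these benchmarks does **not** show: robustness to read-level
artifacts (chimeric reads, reference bias, mapping-quality pathologies),
to assembly errors other than class mislabeling, or to the manual-curation
step that separates raw candidates from final call sets on real data.

## Known limitations

* INDEL de novo mutations are out of scope (consumed only as proximity
  filters); structural variants are not modeled.
* The simulator has no repeat families; the 3× depth cap is exercised only
  by stochastic depth excursions.
* `project_annotation` uses block-linear coordinate transfer from
  12-column PAF; indel-containing alignments would need CIGAR-aware
  transfer.
* The positive-control fraction for re-classified bubble contigs is a
  report, not a hard gate — no published threshold exists for it.
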