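# Methods

## Scope and model

`imprintscan` analyzes locus-specific genomic-imprinting experiments built on
clone-based bisulfite sequencing.  The experimental unit is a short PCR
amplicon (a few hundred bp) over a candidate differentially methylated region
(DMR).  Genomic DNA is bisulfite-converted, PCR-amplified, cloned, and
individual clones are capillary-sequenced, so each read reports the complete
CpG methylation pattern of one chromosome (one epiallele).  The package
covers four analysis stages plus a ground-truthed simulator:

1. **Methylation calling** — align each clone to the in-silico-converted
   amplicon reference, call methylated / unmethylated / missing per CpG,
   score bisulfite-conversion efficiency, filter, and collapse PCR
   duplicates.
2. **Allele-resolved DMR classification** — assign clones to chromosomes at
   a heterozygous SNP inside the amplicon and classify the region as
   differential, hypermethylated, hypomethylated, or intermediate.
3. **Allelic expression** — convert cDNA SNP measurements (pyrosequencing
   allele-quantification fractions or capillary peak heights) into a
   three-tier call: complete monoallelic, preferential monoallelic,
   biallelic.
4. **Imprint-timing inference** — combine sperm, oocyte and somatic evidence
   at one locus into a germline-origin category, and normalize stage-wise
   methylation series to a reference developmental stage.

## Reference conversion and alignment

Bisulfite converts unmethylated cytosine to uracil (read as T) while
5-methylcytosine resists conversion.  On the top strand the converted
reference therefore has every non-CpG C replaced by T, while each CpG
cytosine is genuinely two-valued: C if the source molecule was methylated, T
otherwise.  We encode these positions with the IUPAC code Y (R for the
CpG guanine when reading the bottom strand, where conversion appears as
G→A) and align with a substitution matrix in which the ambiguity code
matches either base at full match score.

Alignment is global with free end gaps (clone reads start and end at
slightly variable points after primer and quality trimming): match +1,
mismatch −1, and affine internal gaps costing −4 for the first gapped
column and −1 for each additional one.  Both the read and its reverse
complement are scored and the better orientation kept; methylation calls are
made in reference coordinates and are therefore orientation-invariant.  The
aligner is `Bio.Align.PairwiseAligner`; its scores are checked in the test
suite against an independently written Gotoh dynamic program on hundreds of
randomized short reads.  Reads whose best alignment matches fewer than 80%
of aligned columns are rejected as unmappable — capillary clones are
near-perfect, so the floor only removes garbage; it is configurable.

## Per-clone statistics

**Methylation calls.** At each CpG, read base C ⇒ methylated, T ⇒
unmethylated; a gap, an uncovered position, or any other base ⇒ missing.

**Conversion efficiency.** Non-CpG cytosines are assumed unmethylated, so a
retained C outside CpG context marks a conversion failure:
`efficiency = 1 − unconverted / total` over covered non-CpG reference-C
positions (gapped positions excluded from both counts).  When no informative
position is covered the statistic is undefined, not zero.  A retained
non-CpG C is formally indistinguishable from a C/T polymorphism; it is
counted against efficiency, and the SNP-discovery stage reports any offset
where a C/T split recurs across clones (flagged unusable for allele
assignment).  The default efficiency filter, ≥ 0.95, sits at the bottom of
the range a well-behaved conversion kit produces; filtering is opt-outable
because a clean experiment may never trigger it.  Clones with fewer than
half the amplicon's CpGs called are also dropped.

**Deduplication.** Byte-identical clone sequences within a sample are taken
to be nonindependent PCR amplificates of one molecule: a single
representative (smallest clone id) is kept and its multiplicity recorded.
All downstream per-sample statistics use unique clones; multiplicity is
retained for reporting and shown beside lollipop rows.

## Allele assignment and DMR status

Allele assignment requires a SNP whose two alleles remain distinguishable
after conversion — C/T pairs on the top strand (G/A on the bottom) collapse,
because the unmethylated C allele also reads as T.  Each usable SNP votes by
comparing the aligned read base to the conversion-adjusted expectation of
either allele (a C allele at a non-CpG SNP is expected as T); majority wins,
conflicts or gaps give `unassigned`.  Without pedigree information the
parental origin of an allele cannot be established, so alleles are labeled A
(reference base) and B (alternate) and the imprint-timing logic never claims
a parental direction beyond what gamete states imply.

DMR status uses pooled per-allele means over called CpGs with thresholds
hi = 0.75 and lo = 0.25: differential when the two alleles straddle both
thresholds, hypermethylated / hypomethylated when they sit on the same side,
intermediate otherwise, and `insufficient_data` below 3 clones per allele.
The thresholds are not measured constants; they are set so that
near-all-or-none clone patterns with sporadic discordant CpGs classify as
differential.  For SNP-less samples an unphased fallback inspects the
per-clone mean-methylation histogram: ≥ 25% of clones above hi and ≥ 25%
below lo is called differential (explicitly marked unphased); otherwise the
pooled mean decides.  A two-mode histogram rule was chosen over a mixture
model because it is transparent and directly testable.

## Expression tiers

The minor-allele fraction (folded to [0, 0.5]) is classified with
`t_complete = 0.10` and `t_biallelic = 0.35` (≤ semantics at both
boundaries).  No numeric cutoffs exist in the assay itself; these defaults
are chosen so that typical allele-quantification noise (~5 percentage
points) cannot promote a truly silent allele past the complete-monoallelic
tier, and they are recorded in every output table.  Individuals homozygous
at the assay SNP are uninformative: excluded from percentages, counted
separately.  A tissue containing both biallelic and monoallelic informative
individuals is flagged as polymorphically imprinted.

## Gamete states and imprint timing

Gamete clone sets are pooled (all molecules of one germline share the
imprint state) and called methylated (mean ≥ 0.8), unmethylated (≤ 0.2) or
intermediate; fewer than 5 unique clones gives `missing`.  Clones are also
binned as fully methylated (≥ 90% of called CpGs), partial, or unmethylated
(≤ 10%), so a couple of discordant clones in an otherwise clean gamete
sample — rare somatic-cell contamination or epimutation — surface as a note
rather than disappearing into the mean.  The 0.8/0.2 thresholds are set so
that an oocyte sample that is ~90% unmethylated reads with a few partially
methylated contaminant clones still calls unmethylated.

The origin decision table over (sperm state, oocyte state, somatic DMR
status) is total: sperm methylated + oocyte unmethylated + somatic
differential ⇒ paternal germline; the mirror ⇒ maternal germline; both
gametes unmethylated + somatic differential ⇒ post-fertilization maternal
acquisition; somatic not differential ⇒ not imprint-like; anything
intermediate or missing ⇒ indeterminate, naming the offending field.  Both
gametes methylated with a somatic differential matches no known
establishment route and is reported indeterminate.

Stage trajectories normalize absolute methylation to a reference stage
(typically ICM/blastocyst): `relative = 100 · absolute / absolute[ref]`,
undefined (flagged) when the reference level is zero, with a
monotone-acquisition flag true when the series is non-decreasing up to the
reference within a 0.05 tolerance.  Stage names are free text with a
caller-supplied ordering, since meta-analysis tables name stages
inconsistently across datasets.

## The synthetic-data generator

The simulator emulates the experimental structure end to end: an amplicon
of configurable length and CpG count carrying at least one usable SNP
(collapsing C/T pairs rejected by default); molecules drawn 50:50 from two
parental epialleles (the maternal chromosome carries the reference SNP base
by convention); per-CpG Bernoulli methylation by the epiallele's
probability (optionally a single draw per molecule in "blocky" mode);
bisulfite conversion with a per-cytosine failure rate (default 0.01, which
reproduces a ~99% mean conversion efficiency downstream) and an optional
inappropriate-conversion rate for methylated CpGs (default 0); substitution
sequencing errors (default 0.002/base); 0–3 bp random end trims emulating
variable capillary read boundaries; PCR duplicates as exact copies of
earlier reads (default rate 0.1 of emitted clones); and optional
contamination of gamete samples by molecules drawn from a somatic epiallele
pair (default 0.04, the scale suggested by finding ~2 discordant clones in
a 46-clone oocyte set).  Only the top bisulfite strand is simulated by
default; bottom-strand (G→A) references and calls are supported throughout
via `strand_mode`.

Three presets encode the imprint-timing groups: paternal-germline (sperm
methylated, oocyte unmethylated, somatic differential), maternal-germline
(the mirror), and delayed-maternal (both gametes unmethylated, somatic
differential).  Preset epialleles use methylation levels 0.98 / 0.02 rather
than exactly 1 / 0: real clone sets show sporadic discordant CpGs within
otherwise uniform epialleles, and all-or-none levels would make distinct
molecules byte-identical, which the deduplication stage would (correctly)
collapse.  Conversion failures are modeled i.i.d. per cytosine; clone-level
clustering of failures is not modeled.  Indels are not simulated
(substitutions and end trims only), chromatograms are out of scope (inputs
are base-called sequences), and no attempt is made to model PCR
amplification bias between alleles beyond the configurable allele ratio.
Consequently, passing tests demonstrate correctness of the analysis logic
under this generative model, not robustness to artifacts the model omits
(indel-rich reads, strand-biased conversion, chimeric PCR products).

## Problem sizes and numerical choices

Simulation-based checks use study-scale sizes: 160 bp amplicons with 12
CpGs and one A/G SNP, 30 molecules per sample (46 for the contaminated
oocyte emulation), 50 replicate studies per preset and noise level, and 200
replicates for parameter-recovery and classifier-power checks.  Parameter
recovery is judged against equal-tailed exact binomial 99% intervals at the
realized number of CpG calls.  All randomness flows through
`numpy.random.default_rng` seeds carried in scenario and config objects;
rerunning any pipeline with the same seed and configuration reproduces every
output byte for byte, and each output embeds a hash of the configuration
that produced it.  Coordinates are 0-based half-open internally and 1-based
in human-readable tables.

## Known limitations

- Parental origin is never asserted without pedigree; "maternal" in the
  origin categories reflects the gamete-state logic, with the somatic
  differential's parental direction assumed from orthologous loci.
- The unphased (SNP-less) DMR fallback cannot separate allelic differential
  methylation from a 50:50 mixture of cell populations.
- Per-clone mixed patterns (possible chimeras) are not flagged; discordant
  CpGs are tolerated implicitly by the classification thresholds.
- The conversion-efficiency statistic attributes every retained non-CpG C
  to conversion failure; a true C/T polymorphism at such a position
  deflates efficiency and is only surfaced via the recurrence warning in
  SNP discovery.
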