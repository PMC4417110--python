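# imprintscan

Allele-resolved analysis of clone-based bisulfite sequencing for genomic
imprinting studies.

Genomic imprinting is parental-origin-dependent monoallelic gene expression,
controlled by differentially methylated regions (DMRs) in which one parental
allele is methylated and the other is not.  Laboratories studying imprinting
at specific loci — in primates, where samples are precious and genome-wide
assays may miss the region of interest — still rely on the classic design:
bisulfite-convert DNA, PCR a few-hundred-bp amplicon over the candidate DMR,
clone, and capillary-sequence individual clones so each read reports one
chromosome's complete CpG methylation pattern.  `imprintscan` turns those
reads, plus cDNA SNP assays, into the study's quantitative results:

- **Methylation calling** — reads are aligned to the in-silico
  bisulfite-converted reference, where every non-CpG C becomes T and each
  CpG cytosine is two-valued ({C, T}, since its fate depends on
  methylation).  Per clone it reports per-CpG calls, the bisulfite
  conversion efficiency `1 − unconverted/total` over covered non-CpG
  cytosines, and collapses byte-identical reads as PCR duplicates.
- **Allele-resolved DMR classification** — clones are tied to chromosomes
  at a heterozygous non-C/T SNP inside the amplicon (C/T pairs collapse
  under conversion and are rejected), and the region is classified
  differential / hypermethylated / hypomethylated / intermediate from the
  per-allele methylation means, with lollipop diagrams (text or SVG).
- **Allelic expression** — pyrosequencing allele-quantification fractions
  or capillary peak heights at cDNA SNPs become three-tier calls (complete
  monoallelic ≤ 0.10, preferential monoallelic ≤ 0.35, else biallelic, on
  the minor-allele fraction) and per-gene, per-tissue summaries.
- **Imprint timing** — sperm, oocyte and somatic evidence combine into a
  germline-origin call (paternal germline, maternal germline,
  post-fertilization maternal, not imprint-like, indeterminate), and
  stage-wise methylation series are normalized to a reference stage
  (percent of the ICM/blastocyst level).
- **A ground-truthed simulator** — amplicons, parental epialleles, clone
  reads with conversion failure, sequencing error, PCR duplication, end
  trims and gamete-sample contamination, so the entire chain runs and is
  validated with no external data.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate and analyze a locus with delayed maternal imprint acquisition —
both gametes unmethylated, somatic tissue differentially methylated:

```sh
$ imprintscan run --preset delayed-maternal --seed 7 --out demo
delayed-maternal: origin = post_fertilization_maternal
```

`demo/` now contains the amplicon (FASTA + JSON sidecar with CpG and SNP
annotations), per-sample clone FASTAs and ground truth, per-clone call
tables, the allelic profile, and the origin call.  The somatic lollipop
diagram shows the two epialleles split at the amplicon's A/G SNP (filled =
methylated CpG, open = unmethylated, `×2` marks a collapsed PCR duplicate):

```
# delayed-maternal-somatic / amplicon-L160-cpg12-s7
allele A (n=12):
  ●●●●●●●●●●●●  delayed-maternal-somatic|clone005
  ●●●●●●●●●●●● ×2  delayed-maternal-somatic|clone008
  ...
allele B (n=16):
  ○○○○○○○○○○○● ×4  delayed-maternal-somatic|clone006
  ○○○○○○○○○○○○ ×2  delayed-maternal-somatic|clone000
  ...
```

and `origin_calls.tsv` records the decision and its inputs:

```
locus             sperm_state   oocyte_state  somatic_status  origin
delayed-maternal  unmethylated  unmethylated  differential    post_fertilization_maternal
```

meaning: neither gamete carries methylation at this DMR, yet somatic tissue
is differentially methylated, so the imprint must be established after
fertilization.  The same stages are available individually
(`imprintscan simulate / meth-call / allele-split / dmr-classify / lollipop /
express-classify / imprint-classify / trajectory`) for real clone FASTAs and
expression tables; every output embeds a hash of the configuration that
produced it, and identical seeds reproduce identical bytes.

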