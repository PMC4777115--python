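# triovar

Family-trio whole-genome variant filtering for autosomal recessive
Mendelian disorders.

## The problem

For a rare fully penetrant recessive disease, sequencing a single family
trio — an affected offspring and both healthy parents — is enough to
shrink millions of called variants to a handful of candidates, without a
genome-wide association study. Both parents are obligate heterozygous
carriers and the affected offspring is homozygous for the causal allele,
so a simple conditional genotype filter, combined with quality filtering,
consequence annotation and known-variant subtraction, carries almost all
of the discriminating power. The motivating application is hereditary
footpad hyperkeratosis (HFH) in Kromfohrländer dogs, where this strategy
isolates the *FAM83G* missense variant c.155G>C (p.R52P) on CanFam3.1
chr5:41,055,619.

`triovar` re-implements that filtering funnel as a tested, reusable
library and command-line tool:

1. **Hard site filters** — fail a site iff MQ < 40, QD < 2.0,
   FS > 60.0 (SNV) / 200.0 (indel), or ReadPosRankSum < −8.0 (SNV) /
   −20.0 (indel); comparisons are strict and absent metrics never fail.
2. **Consequence classification** — codon-level translation against
   transcript models (both strands) into missense / nonsense / silent /
   frameshift / in-frame / non-coding, with HGVS-style `c.`/`p.` names.
3. **Recessive conditional filter** — keep sites with sire HET, dam HET,
   affected offspring HOM-ALT.
4. **Known-variant subtraction** — exact (chrom, pos, ref, alt) matching.
5. **Deleteriousness threshold** — externally supplied SIFT-style scores,
   deleterious iff score < 0.05, applied to missense candidates.
6. **Inspection flags** — manual read-level review modelled as an input.
7. **Cohort concordance** — a variant co-segregates iff every case is
   homozygous alt and no control is (carrier controls allowed), plus
   cross-breed panel exclusion.

A synthetic-data module generates complete study inputs (genome, GTF,
trio VCF with GATK-style metrics, known set, scores, cohort) with one
planted causal variant and decoys engineered to die at every funnel
stage, recorded in a truth table.

## Worked example

Simulate a study and run the full funnel:

```bash
triovar simulate --seed 1 --out fixtures --decoys 1000
triovar run --vcf fixtures/trio.vcf --ped fixtures/trio.ped \
    --gtf fixtures/genes.gtf --fasta fixtures/genome.fa \
    --known fixtures/known.vcf --scores fixtures/scores.tsv \
    --inspection fixtures/inspection.tsv --out out
cat out/funnel.tsv
```

```
stage	snv	indel	removed	breakdown
called	871	130	0	
hard_filter	782	118	101	
exonic	193	0	707	missense=129;nonsense=5;silent=59
conditional	123	0	70	missense=75;nonsense=3;silent=45
novel	56	0	67	missense=33;silent=23
deleterious	11	0	45	
inspection	1	0	10	
```

Reading the funnel: 1,001 simulated sites are reduced to a single final
candidate — the planted causal missense variant, which
`out/candidates.tsv` reports as `chr4:32947 A>G` in `gene_0034`,
category `missense`, `c.50T>C` / `p.V17A` (a minus-strand gene, so the
coding alleles are complemented), score 0.01, inspection pass. Each row is one
filter stage; `removed` is the count eliminated by that stage and the
breakdown partitions coding SNVs, so missense + nonsense + silent always
equals the stage's SNV total.

The packaged validation tables for the HFH candidate variants are
available directly:

```bash
triovar concord
```

prints per-variant verdicts: the *FAM83G* column and both *GRAPL*
positions are `concordant` (all 8 cases homozygous, no control
homozygous), while *PDILT*, *DLGAP2*, *TDRD6* and *USP4* are
`nonconcordant` with the offending samples listed.

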