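# Methods

## Model and assumptions

`triovar` implements candidate-variant discovery for a fully penetrant
autosomal recessive monogenic trait from a single sequenced family trio.
The inheritance model fixes the genotype configuration at the causal
site: both healthy parents are obligate heterozygous carriers and the
affected offspring is homozygous for the alternate allele. The pipeline
is a deterministic funnel of predicates; there is no statistical test
and no likelihood model. Consequently:

- the approach assumes full penetrance and no phenocopies — a single
  discordant genotype in the validation cohort refutes a candidate;
- locus heterogeneity is out of model (one causal site is sought);
- de novo, dominant and compound-heterozygous mechanisms are not
  covered — a site where one parent is homozygous reference is discarded
  even though the offspring could be affected under compound
  heterozygosity across sites.

All records are biallelic; multiallelic VCF rows are split one record
per alternate allele. In the split, genotype alleles equal to the target
alternate become 1, reference stays 0, and any *other* alternate becomes
missing — a conservative recoding, since such a sample can satisfy
neither the HET nor the HOM-ALT requirement for the target allele.
Half-calls and non-diploid GT strings map to missing; a record with any
missing trio genotype never passes the conditional filter.

Coordinates are 1-based inclusive everywhere (the VCF/GTF convention);
no half-open interval type is exposed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `mq_min` | 40 | RMS mapping quality floor (unitless) |
| `qd_min` | 2.0 | quality-by-depth floor |
| `fs_max_snv` / `fs_max_indel` | 60.0 / 200.0 | Phred-scaled strand-bias ceiling |
| `rprs_min_snv` / `rprs_min_indel` | −8.0 / −20.0 | read-position rank-sum Z floor |
| deleterious threshold | 0.05 | SIFT-style score below which a missense change is called deleterious |

These are the standard GATK hard-filter recipe values and the
conventional SIFT cutoff. All comparisons are strict, so a value exactly
at a threshold passes; an absent metric never triggers its filter
(callers emit ReadPosRankSum only at sites with heterozygous support, so
absence means "not applicable"). Indel thresholds are looser than SNV
thresholds by construction and the `FilterThresholds` type enforces that
ordering.

Failing records are annotated with every violated filter label and
retained in a side channel (flag-not-delete, as GATK VariantFiltration
does); downstream stages consume only the passing set, which keeps the
funnel arithmetic well-defined.

## Consequence classification

The classifier maps a genomic SNV to its coding-nucleotide position by
walking the transcript's CDS intervals (descending with complemented
alleles for minus-strand transcripts), substitutes within the affected
codon, and translates with a hardcoded standard genetic code
(unit-tested codon-by-codon against Biopython's table). Codon index is
`ceil(cds_pos / 3)`. Coding SNVs partition exactly into missense /
nonsense / silent; indels touching the CDS are frameshift iff the length
change is not a multiple of 3. Initiator-codon loss and stop-loss are
reported as missense with an explanatory flag (`start_loss`,
`stop_loss`, the latter with alt residue `X`) to preserve the three-way
SNV partition; splice regions, UTRs and introns are all non-coding, the
granularity the funnel needs. A record overlapping several transcripts
carries all consequences and is summarised by the most severe
(frameshift > nonsense > missense > in-frame > silent > non-coding).

Correctness is established two ways: the incremental codon
classification is compared against an independent oracle that translates
the entire mutant versus reference CDS with Biopython and diffs the
proteins (1,000 random SNVs on both strands per run), and a strand
involution property checks that classifying on a minus-strand transcript
equals classifying the reverse-complemented locus on the mirrored
plus-strand transcript.

## Downstream triage decisions

- **Known-variant subtraction** matches on exact (chrom, pos, ref, alt),
  not position: a novel allele at a known polymorphic site remains a
  candidate.
- **Deleteriousness** applies to missense candidates only — the score
  models an amino-acid substitution — so silent and other categories are
  dropped at this stage, as are missense candidates with no score (with
  a warning). This matches a funnel in which only novel missense changes
  proceed to functional prediction.
- **Inspection** is an externally supplied per-variant pass/fail flag
  standing for manual read-level review; it is an input, never a
  computation. With no flag file the stage is the identity; a candidate
  absent from a supplied flag file is kept (uninspected is not refuted).
- **Concordance** is recessive: every case homozygous alternate, no
  control homozygous alternate; heterozygous carrier controls are
  expected under the model and allowed. Missing case genotypes break
  concordance (the pattern cannot be demonstrated); missing control
  genotypes are ignored with a warning. Panel exclusion flags any
  candidate for which an unaffected genome is homozygous alternate.

## Synthetic data

The generator emulates the study design, not sequencing physics. It
draws a uniform-random genome (default 5 chromosomes × 100 kb) with 50
non-overlapping 3-exon coding transcripts on both strands, plants
exactly one causal missense variant that satisfies every stage (pattern
genotypes, passing metrics, score 0.01, unknown, inspection pass), and
surrounds it with 5,000 decoys each engineered to die at a designed
stage:

- metric failures (10% of decoys): one metric pushed past its threshold,
  chosen uniformly so every filter label is exercised;
- non-exonic decoys (the bulk): placed outside every CDS;
- coding decoys (20% of the remainder, sub-split as 30% known — the
  `fraction_known` default — and of the rest 50% wrong inheritance
  pattern, 20% silent, 15% non-deleterious missense, 5% unscored
  missense, 10% deleterious-but-inspection-failed missense), so every
  elimination path downstream of the exonic stage is populated.

Trio genotypes are Mendelian-consistent at every site (offspring alleles
drawn from the parents); wrong-inheritance decoys are Mendelian draws
rejected until they fail the het/het/hom-alt pattern, so no site is
Mendelian-impossible. Site metrics come from rounded truncated normals
(MQ 55 ± 5, QD 20 ± 6, FS 3 ± 3, ReadPosRankSum 0 ± 1.5, clipped into
the passing region for non-failing decoys); ReadPosRankSum is emitted
only at sites with a heterozygous call, mimicking caller behaviour. The
known-variant VCF adds never-simulated sites and same-position
different-allele entries to exercise the allele-exact matching rule. The
cohort table gives every case the homozygous causal genotype, carriers
among controls at rate 0.2, and at least one concordance-breaking
genotype in every decoy column. The truth table records each variant's
designed elimination stage and is the end-to-end oracle: the observed
stage at which the pipeline drops each variant must equal it.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level errors and systematic
mapping artefacts (metrics are independent draws, not functions of
alignments), linkage disequilibrium and realistic allele-frequency
spectra, multi-nucleotide and structural variants, non-left-aligned
indel representation, population structure in the cohort, and annotation
ambiguity from overlapping real gene models. Genotyping error exists
only where a decoy is designed to model it.

Determinism: genotypes use Python's integer RNG, metrics are rounded to
two decimals, and all outputs are sorted, so a fixed seed reproduces the
fixture set byte-for-byte across platforms.

## Problem sizes and numerics

The default simulation (5,001 variants, 50 genes, 500 kb genome) runs
the full pipeline in a few seconds on one core; the test suite uses 400
decoys for unit-level checks and 5,000 for the end-to-end properties,
sizes at which every elimination path is populated many times over.
VCF INFO floats are stored as float32 by htslib, so round-trip equality
of metrics is asserted to 1e-6 relative tolerance; all filter
comparisons happen on the parsed values, not on re-rendered text.
Funnel reports validate non-increasing totals and breakdown sums on
construction; inconsistent stage order is an error, never silently
reordered.

## Known limitations

- Single-trio, single-model design: no support for multiple affected
  siblings, dominant or compound-heterozygous filters.
- Indels are used as written (no left-alignment); a shared ref/alt
  prefix longer than one base logs a warning instead of normalising.
- HGVS names cover coding SNVs (`c.`/`p.`); indel HGVS naming is not
  generated.
- The deleteriousness and inspection inputs are consumed, never
  computed; their quality bounds the pipeline's precision exactly as in
  the original study design.
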