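# Methods

## Region catalogs

Coordinates are 0-based half-open internally; GTF input and output use the
standard 1-based inclusive dialect, converted only at the I/O boundary.
Only `exon` features contribute coordinates; a gene's span is the union of
its exons (no explicit `gene` line is required), and its biotype is taken
from the `gene_biotype`/`gene_type` attribute (`protein_coding` → mRNA,
`lincRNA`/`lncRNA` → lincRNA, anything else → other).

**Introns** are the gaps between a gene's *merged* exons: exon records of
different transcripts of one gene overlap freely, so they are collapsed to
a minimal disjoint set first. Gaps of length zero (abutting exons) produce
no region. Introns inherit the gene's strand and get deterministic ids
`<gene_id>:intron:<ordinal>` numbered along the genome. Exons of *other*
genes are not subtracted by default — introns are a within-gene concept
here; the `mask_foreign_exons` flag (CLI `--mask-foreign-exons`) enables
the subtraction for annotations with many nested genes.

**Intergenic regions** are the gaps between merged gene blocks per
chromosome, strand-ignored and emitted unstranded: overlapping or nested
genes merge into one block, so no region is emitted between them. Flanks
before the first and after the last gene of a chromosome are not emitted;
this keeps the definition "between genes" and avoids needing chromosome
lengths. Ties between identical spans are broken by (start, end, gene_id),
so region ids are reproducible across runs regardless of input order.

## Union-mode counting

The counter reproduces the union-mode semantics of htseq-count: a fragment
overlapping exactly one region (on a compatible strand) increments it; a
fragment hitting ≥ 2 regions is discarded as ambiguous; one hitting none is
unassigned. `assigned + ambiguous + unassigned + unknown_chromosome` always
equals the number of fragments processed. Strand handling follows the dUTP
reverse-stranded protocol (`RF`): a fragment's originating transcript lies
opposite its first read's alignment strand, so under `RF` the recorded
strand is flipped before comparison with the region strand; unstranded
regions (intergenic) accept both. Mates of a pair are unioned into one
block list and counted once; secondary/supplementary/unmapped SAM records
are skipped. Duplicate fragments are counted as given unless
`drop_duplicates` is set (off by default — genotype-level duplicate
removal is an upstream concern).

A region is "expressed" in a sample iff its raw count reaches a threshold.
The threshold is a sensitivity knob with default 1 read; the expressed-
proportion trends it feeds are qualitative, and no claim depends on the
specific value.

## Parental-origin pipeline

Genotypes are alt-allele dosage codes (0/1/2, −1 = missing). Only
bi-allelic SNVs enter the analysis: records still multi-allelic on input
and indels are skipped with a logged tally.

*Breed-specific SNP rule.* All maternal-breed parents `0/0` with all
paternal-breed parents `1/1`, or the mirror; any heterozygous or missing
parental call excludes the site. With three sequenced parents per breed
this approximates fixation for opposite alleles in the two breeds.

*Filter cascade.* Three ordered predicates (allele mismatch between the
DNA- and RNA-derived callsets; within-stage replicate discordance;
maternal–oocyte mismatch). Each predicate is a pure function of the site,
so the surviving set is provably invariant under reordering — only the
per-step attribution (first failing filter wins) changes, which the cascade
report records. A missing genotype at a stage neither discords nor removes:
only two differing non-missing calls within one stage do, and origin at a
stage without a concordant call is `undetermined`. The oocyte filter reads
"mismatch" as the oocyte RNA genotype containing an allele the maternal DNA
genotype lacks; a heterozygous oocyte call therefore fails it. This filter
deliberately breaks maternal/paternal symmetry — the oocyte transcriptome
anchors which breed is the dam — so the symmetry guarantee (relabelling the
breeds mirrors every call) is stated over the two symmetric filters plus
classification, and with the full cascade a swapped run removes every site
at the oocyte step.

*Site→origin rule.* At a surviving site the F1 DNA is obligate
heterozygous, so RNA homozygosity is mono-allelic expression: homozygous
maternal allele → maternal, heterozygous → biallelic, homozygous paternal
allele → paternal. The mapping is the minimal rule consistent with the F1
design; no expression-level threshold is involved because the input is a
genotype call, not allele counts.

*Gene summary.* A marker supports a gene iff it falls inside exactly one
gene span (introns included, since markers are validated on pre-mRNA);
markers in zero or ≥ 2 overlapping genes are dropped as unannotated. Genes
need ≥ 2 supporting markers (`single_snp` filter), and all markers of a
gene must agree at every stage where they have determined calls
(`inconsistent_pattern` filter). Filter order: unannotated → single_snp →
inconsistent_pattern. Stages where no marker has a call are
`undetermined`, not inconsistent.

## Synthetic cross

The generator's defaults encode the study design the pipeline targets: two
chromosomes, 50 genes (2–6 exons, ~20% lincRNA, one deliberately
overlapping antisense gene pair), two breeds with three sequenced parents
each, five stages (oocyte, zygote, EGK.III, EGK.VI, EGK.X) in biological
triplicate, 300 breed-fixed sites spread evenly over gene spans plus 100
shared-polymorphic decoys (each forced to carry ≥ 1 heterozygous parent so
it is never breed-specific by construction), and reads of 150 bp matching
paired-end 150 bp sequencing. The planted origin program is maternal-only
at every stage before EGK.X and bi-allelic at EGK.X, with a 5% residual
gene set that stays maternal throughout — the qualitative pattern the
pipeline exists to detect. Stage-specific intronic read fractions (0.05 /
0.25 / 0.10 / 0.30 / 0.30 across the five stages, intergenic constant at
0.02) are free parameters chosen to give a clear two-wave profile; no
quantitative effect size is asserted for them.

Error models: genotype error corrupts a call to a uniformly chosen
different genotype with probability *e* per call (applied to parents and
embryos alike); RNA dropout removes a site from an embryo's callset with
probability *d*. Both default to 0 so that the clean-data guarantee (100%
recovery of the planted program for every unfiltered gene) is exact.
Determinism: every generator draws from `numpy` Generators seeded as
`[seed, stream]` with a fixed stream id per stage, so one config seed fixes
every output byte.

What the generator does **not** emulate: sequence-level reads (no FASTQ,
no aligner, no base qualities), spliced read blocks, allelic read-count
imbalance (expression is expressed only through the genotype call, as in
the pipeline's input contract), linkage between neighbouring sites, and
reference-mapping bias. Passing tests therefore validate the arithmetic,
bookkeeping and inference rules — not robustness to alignment artefacts in
real data.

## Verification design

Three independent oracles back the guarantees: (1) region catalogs and the
union-mode counter are compared with exhaustive integer base-set
enumeration (`zga_ase.oracles`) on randomized small instances; (2) cascade
bookkeeping is checked on planted-defect sets with disjoint violations,
where the report is known by construction; (3) post-filter miscall and
survival rates under genotype error are compared with a direct Monte-Carlo
simulation of the corruption process (`predict_miscall_rate`) that shares
no code with the pipeline path, at 3-binomial-SD tolerance. Problem sizes
(100 random annotations of ≤ 20 genes, 5 × 10³-read counting instances, the
50-gene default cross) keep the full suite under ten seconds while leaving
every check statistically meaningful.

## Known limitations

- Genotype-level only: allele-specific read counting from BAM, and hence
  partial imbalance between alleles, is out of scope; origin calls are
  categorical per stage.
- The breed-specific rule requires fixation in the sampled parents; rare
  within-breed polymorphism at a marker shows up only through the cascade
  filters.
- Intron definitions ignore exons of other genes unless
  `mask_foreign_exons` is set, so intronic counts inside dense nested loci
  can include foreign exonic signal.
- No differential-expression testing or normalisation: the count matrices
  are emitted for downstream count-based DE tools.
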