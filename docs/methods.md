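# Methods

## Model

The pipeline targets the classic F1 pseudo-testcross design for sex-marker
discovery in a dioecious species: two outbred parents and their full-sib
progeny are RAD-sequenced, and a SNP is a sex-marker candidate when its
genotypes split perfectly by sex. Under female heterogamety (ZW/ZZ) a SNP in
the non-recombining sex-determining region has its alternate allele confined
to the W haplotype: the mother and every daughter are heterozygous, the
father and every son homozygous for the reference allele. Under XX/XY the
pattern mirrors onto the Y. The inference rule is strict: at least one
candidate and *all* candidates female-heterogametic → ZW; all
male-heterogametic → XY; anything else → undetermined.

The screen is an exact-match filter, not a statistical test. Its
false-positive load is governed by family size: an informative autosomal
locus (one parent het, the other hom) produces a perfect progeny sex-split
with probability `2·(1/2)^(n_f + n_m)` — each progeny is independently
heterozygous with probability 1/2, and either sex can be the all-het one.
For the default 8 + 8 design that is 3.05 × 10⁻⁵; with ~10⁴ informative loci
the expected false-candidate count is ~0.3. The package reports this number
alongside every screen and verifies it by Monte Carlo (the Monte Carlo
screens progeny only, which is the population over which the closed form is
defined; in the full cross screen the parents participate too — the mother
must herself be het for a female-heterogametic candidate — which removes one
of the two orientations).

## Synthetic library

The generator produces data with exactly the statistical structure the
pipeline assumes, so every stage can be tested without external data.

* **Genome.** Random uniform ACGT sequence; EcoRI `GAATTC` sites are
  *planted* on a ≥100-nt grid (so 82-nt tag windows never overlap) and
  accidental occurrences are scrubbed, making the realised site count equal
  to the plan. A contiguous interval (default 20% of the genome) is
  designated the sex-determining region; its placement is random.
* **Variants.** Biallelic substitutions on tag positions 6–82 (never inside
  the residual `AATTC`), at most two per tag. Sex-linked variants go on tags
  fully inside the sex region; autosomal variants outside. Autosomal
  parental configurations are drawn as mother-het (0.4), father-het (0.4),
  both-het (0.1), hom-ref (0.1): the pseudo-testcross configurations
  dominate because they are the informative ones, while both-het and hom-ref
  loci exercise the parent-polymorphism filter (hom-ref loci are invisible
  to a de novo pipeline, and the evaluation treats their absence from the
  genotype matrix as implied hom-reference calls).
* **Cross.** Progeny sex counts are fixed (balanced) by default, mirroring
  the usual balanced sampling design; a `balanced=false` mode draws sexes
  Bernoulli(1/2). Sex-linked alleles are inherited deterministically with
  the W (or Y); autosomal alleles are drawn independently per variant
  (free recombination between tags). A ZW×ZZ cross can produce no WW
  individual, and the generator asserts this.
* **Reads.** One tag per usable cut site, plus strand only, as
  `MID + AATTC + 77 nt`: 8-nt barcodes are generated with pairwise Hamming
  distance ≥3. Depth is Poisson(mean_depth/2) per haplotype so a
  heterozygote's two alleles are sampled independently. Substitution errors
  are applied uniformly over the whole 90-nt read (including the barcode —
  so a realistic fraction of reads is lost at demultiplexing). Qualities
  are constant Q30 because no stage uses them; indels, PCR duplicates,
  paired-end mates and shearing/size selection are out of model.
* **Truth.** Every run emits a per-variant × per-individual genotype truth
  table and a manifest with all parameters and the seed. Identical
  (config, seed) runs are byte-identical.

What the generator does **not** emulate: allele-specific amplification bias,
depth overdispersion beyond Poisson, restriction-site polymorphism (allele
dropout from mutated cut sites), repetitive DNA, and indel variation.
Passing tests on this generator therefore demonstrate the correctness of
the pipeline's logic under its own model assumptions, not robustness to
every pathology of real libraries.

## Tag assembly

Within an individual, unique 82-nt read sequences are clustered greedily
around abundance-ranked seeds (ties broken lexicographically, making runs
reproducible) with a 2-mismatch radius; stacks below `min_stack_depth`
(default 3) reads are set aside as residual. Across individuals, stack
consensuses are merged by single linkage at `catalog_mismatch` (default 2)
into catalog loci; the reference consensus is the column-majority over
parent-derived stacks when present. A locus where any individual
contributes more than two distinct consensuses is flagged repetitive
(putative paralog collapse) and excluded from genotyping.

One consequence of a 2-mismatch radius is that the two alleles of a
heterozygote — which differ at one or two positions — fall inside a single
stack. Stacks therefore retain per-column base counts, and all downstream
allelic analysis (variant-position detection in the catalog, genotype
calls) operates on column depths rather than on whole-stack alleles. This
is also why indels are out of model: tags are fixed-length and columns are
positionally homologous by construction.

## Genotyping

At each variant column, a per-individual call is made from the 4-vector of
base depths: missing (`low_depth`) if the top base has fewer than
`min_allele_depth` reads; heterozygous if a second base reaches
`min_allele_depth` and `min_minor_ratio` of the major depth (three such
bases → missing `repetitive`); otherwise homozygous for the major base,
with an `allele_imbalance` annotation whenever a minor base was seen.

Defaults are `min_allele_depth = 2`, `min_minor_ratio = 0.1`, sized
analytically for the 20–60× tag depths this design targets. Each allele of
a het is sampled Poisson(depth/2): at 20×, requiring three minor reads or a
0.25 ratio would miscall ~1–2% of true heterozygotes as homozygous
(P[min < 3 or min/max < 0.25] ≈ 0.01 for iid Poisson(10) pairs, before
demultiplexing losses), which both degrades concordance and, compounded
over the ~45 heterozygous cells of the sex screen, frequently destroys one
perfect-cosegregation pattern. At (2, 0.1) the miscall rate falls to the
irreducible Poisson(≤1) tail (~0.2% per het cell), while an error-derived
minor allele — expected at ~ε/3 ≈ 0.17% of column depth per wrong base —
essentially never reaches two reads *and* a tenth of the major depth.
There is no likelihood model (the library carries no informative
qualities); a binomial-likelihood caller is a natural extension point.

The remaining stochastic limit is worth stating: when a true allele draws
≤1 read (probability ~9 × 10⁻⁴ per allele at 20× after demultiplexing
losses), no caller can rescue it. Across the 45 sex-linked heterozygous
cells of the default demo, roughly 1 run in 13 loses one planted marker to
this tail; the loss disappears at ≥30× depth.

## Screen and reporting

The parent filter keeps a (locus, position) only when both parents are
called and differ. The screen then demands, over the screened individuals
(those with sex labels; missing calls tolerated up to `max_missing`,
default 0 for this deeply covered design): one identical het genotype in
every female and one identical hom genotype — whose base belongs to the het
pair — in every male, or the mirror. Candidates are reported with the
standard IUPAC ambiguity code (R/Y/S/W/K/M), the 82-nt tag sequence with
the SNP bracketed, 1-based coordinates counting from the leading A of
`AATTC`, and a complement-strand code column: single-base extension assays
read from the reverse primer report the complementary alleles, and
published marker tables mix the two orientations, so both are emitted.
Validation-panel scoring applies the rule "het → heterogametic sex, hom →
other sex" to an independent genotype table and flags markers at 100%
accuracy as validated, tallying missing calls separately.

## Summary table

The sequencing summary reproduces the conventional per-individual
accounting for a fixed 82-bp read: total RAD sequence = reads × 82,
total tag sequence = tags × 82, coverage depth = reads/tags, sequence
coverage = total RAD sequence / genome size (genome size is a parameter;
660 Mbp, the pistachio flow-cytometry estimate, is the default), and
bp-per-SNP = total tag sequence / SNP count. Rounding is decimal half-up at
printed precision (one decimal for ×-columns, two for GC%). Group
subtotals and averages of the ratio columns aggregate the *unrounded*
per-individual ratios and round once — published tables behave this way
(subaverage depth is a mean of ratios, not a ratio of sums), and Decimal
arithmetic keeps the reproduction exact. The bundled reference dataset is
the published 18-plant pistachio run, stored as raw inputs only (read/tag/
SNP counts and marker tag sequences); every derived number is recomputed.
One published density figure (one SNP per 418 bp in females) is not
reproducible from any aggregate of the printed inputs (the subaverage
method gives 417) and is not asserted anywhere.

## Problem sizes and numerical choices

The demonstration cross uses a 100-kb genome with 150 cut sites, 205
planted SNPs, 18 individuals and 20× tag depth (~54,000 reads, ~4 s end to
end); the false-positive calibration uses 10⁴ informative loci. These sizes
give tight checks (3,690 truth cells; expected 0.3 false positives) while
keeping the whole suite interactive. Determinism is end to end: one master
seed feeds named substreams (genome, variants, cross, barcodes, reads), all
dictionary iterations are ordered, and clustering tie-breaks are
lexicographic.

## Known limitations

* Single-end, fixed-length, indel-free model; no reference mapping.
* Paralogs are only guarded by the >2-allele exclusion, not resolved.
* The screen requires perfect cosegregation; one miscalled individual
  removes a true marker (no tolerance parameter other than `max_missing`
  for missing calls). This matches the discovery design it implements but
  is fragile at low depth, as quantified above.
* Validation panels are modelled purely as genotype tables; assay chemistry
  (primer design, extension, melting analysis) is outside scope.
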