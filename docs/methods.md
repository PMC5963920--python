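# Methods

## Model and assumptions

The pipeline targets a fully penetrant autosomal-recessive trait in a
nuclear family whose parents are first cousins. Under that model the two
disease alleles of an affected child are identical by descent (IBD), copied
from one chromosome of a shared grandparent, so every affected sibling is
homozygous for the same haplotype across the disease locus. Biallelic SNP
arrays cannot distinguish IBD from identity-by-state directly; the
operational surrogate used throughout is **shared, allele-identical
homozygosity of sufficient genetic length**, refined by exclusion against
unaffected relatives. The expected prior autozygous genome fraction of
first-cousin offspring is the inbreeding coefficient F = 1/16, and the
expected tract lengths around any autozygous point are set by the number of
meioses in the consanguinity loop (six per affected child; eight govern the
jointly shared tract of two affecteds), on the order of 10–30 cM — hence a
minimum-length filter in centimorgans is the natural noise cut.

## Run-of-homozygosity calling

A run is a **maximal** stretch of consecutive markers that begins and ends
on homozygous calls and contains at most `max_het_in_run` heterozygous and
`max_missing_in_run` missing calls; runs with fewer than `min_markers`
markers or spanning less than `min_length_bp` are discarded. Hard per-run
counts (rather than sliding-window densities) were chosen because they are
exactly checkable against brute-force enumeration of all maximal qualifying
windows, which the test suite does on thousands of random genotype strings.
One consequence is embraced rather than hidden: with nonzero tolerances two
maximal runs may overlap (`hom het hom het hom` with one het allowed yields
two runs sharing the middle marker); at zero tolerance runs are provably
disjoint. Defaults — 25 markers, 1 het, 2 missing, 1 Mb — suit a dense
array with a ~99% call rate, where isolated heterozygous calls inside a
long autozygous tract are far more likely genotyping errors than real
recombination signals. All are configurable.

## Candidate-region delineation

Candidate regions are maximal intervals in which **every in-region marker
lies within some qualifying run of every affected individual** (union
coverage) and no marker shows *discordant homozygotes* among affecteds.
Two design points deserve explanation:

- **Union coverage versus single-run containment.** Requiring one single
  run of each affected to cover the whole region looks natural but
  interacts badly with hard per-run tolerance counts: a 25-Mb autozygous
  tract spans ~800 markers at default simulation density and accrues ~4
  missing and ~2 heterozygous calls per affected, so no single run with a
  budget of 1 het/2 missing covers it and the locus fragments. Union
  coverage — every marker supported by *some* qualifying run — keeps the
  locus whole while still demanding locally qualifying homozygosity
  everywhere. The literal single-run behaviour remains available
  (`MappingConfig(containment="single_run")`).
- **Splitting only at violations.** An isolated heterozygous or missing
  call never splits a region (the run machinery absorbs it); two affecteds
  homozygous for *different* alleles is positive evidence against shared
  descent and always splits, regardless of tolerances. A flag
  (`require_affected_identity=False`) relaxes the identity requirement to
  co-occurring homozygosity for analyses that want it.

Region ends snap inward to markers where all affecteds are homozygous for
the shared allele; no extension into inter-marker gaps is claimed.
`concordance` records the fraction of informative in-region markers with
fully shared homozygosity (1.0 in noise-free data).

## Unaffected exclusion

For each unaffected member, maximal runs (same tolerances) of markers where
that member is homozygous for the affecteds' shared allele are assembled;
in `subtract` mode (default) their union is removed from each candidate,
with boundaries re-snapped to retained markers, while `drop` discards any
overlapped candidate wholesale. Requiring *allele identity* (not mere
homozygosity) is the default because a sibling homozygous for the opposite
allele does not disprove linkage; the stricter reading is available
(`unaffected_match="any_hom"`). Subtraction can split one region into two,
so region *count* may grow at this stage; the monotone quantity along the
pipeline is covered base pairs, which every stage can only shrink.

## Genetic length

Genetic length of a region is cM(end) − cM(start) by piecewise-linear
interpolation of bp↔cM anchors, extrapolating terminal interval rates
outside the anchored range; chromosomes without anchors fall back to a
constant 1 cM/Mb, the genome-wide average, which makes the 5 cM confidence
filter usable without an external map. Regions of at least
`min_genetic_length_cM` (default 5.0, inclusive) survive.

## Variant prioritization

Within the final regions (closed 1-based intervals), homozygous variants
are kept if their population MAF is below `maf_max` (default 1%) — a
variant with *no* recorded frequency passes, because for a private mutation
absence from databases is itself the evidence of rarity — and, when
known-polymorphism exclusion is on, if they are not catalogued
polymorphisms above a separate `known_polymorphism_maf` bar (default 10⁻⁴).
The two thresholds are deliberately independent: the exome-wide rarity
filter and the in-region "previously catalogued" filter answer different
questions. Segregation requires every affected homozygous-alternate, every
genotyped parent of an affected heterozygous, and no unaffected
homozygous-alternate; a missing family genotype raises a distinct
incomplete-data signal rather than returning false. Ranking orders
segregation-consistent variants first, then private (non-catalogued) ones,
then ascending MAF with absent MAF ranking rarest, tie-broken by
(chromosome, position) for determinism.

## The simulator

`simulate_study` builds the study design mechanistically: four founders
(one shared grandparental couple, two married-in spouses), the first-cousin
loop by explicit meioses, and a sibship of five with two affected.
Transmission follows the Haldane model — crossover counts Poisson with
mean equal to the chromosome's length in Morgans, positions uniform in
genetic distance, no interference — applied to both allele and
founder-origin arrays so autozygosity is read directly off origin labels.
Defaults emulate a single 150-Mb chromosome with 5,000 markers (~30 kb
spacing), founder minor-allele frequencies uniform on [0.05, 0.5], 0.2%
genotyping error (one allele of a call flipped) and 0.5% missingness,
matching >99% array call rates.

Causal descent is forced by rejection sampling over *individual meioses*
(each conditioned gamete redrawn until it carries — or, for unaffected
children jointly, does not doubly carry — the causal grandparental
haplotype at the locus). Because the conditioning events are functions of
disjoint meioses, this preserves the recombination model's tract-length
distributions exactly.

Two construction guarantees define a well-posed study:

- the **identifiable region** — the affecteds' shared causal tract minus
  any stretch (≥ 1 Mb) where an unaffected sibling is also autozygous for
  the causal haplotype, computed on noise-free origins — must reach
  `min_truth_length_cM` (default 5.0, the mapping threshold). A
  sub-threshold implant is undetectable in principle (the affected shared
  tract is Gamma(2, 8/Morgan), so ~6% of unconditioned draws fall below
  5 cM), and flanks shared with healthy siblings carry no mapping
  information — a correct mapping removes them.
- the causal locus must lie at least `causal_margin_bp` (default 1 Mb, one
  ROH-resolution unit) interior to that region: at the very edge, chance
  identity-by-state lets the exclusion segment of an unaffected overshoot
  its true tract boundary by a few markers and clip the variant out, a
  resolution limit of marker-grid mapping rather than a detection failure.

The descent is redrawn (bounded retries) until both hold; `truth_regions`
records the identifiable region snapped to the marker grid. The variant
table carries the causal variant (absent MAF, not a catalogued
polymorphism, genotypes from true descent) among background variants drawn
from the founder frequency law with catalogued-polymorphism flags. All
randomness flows from one generator seeded once, so equal seeds give
byte-identical output files.

**What the simulator does not emulate:** linkage disequilibrium among
markers (founder haplotypes are drawn marker-wise), crossover interference,
realistic allele-frequency spectra or array ascertainment bias, genotyping
error that correlates across samples or sites, and any sequencing-level
noise in the variant table. Passing tests therefore demonstrate
correctness of the mapping logic under the stated generative model, not
performance on a real array, where LD-induced identity-by-state runs would
make short chance candidates somewhat more common than simulated.

## Numerical and degenerate-input choices

Coordinates are 1-based with closed intervals everywhere, including the
BED-like region output (stated in its header comment). Chromosome labels
compare literally, with an optional normalization switch. Half-missing
calls are treated as fully missing. An empty candidate list, or a variant
table with a header only, are valid outcomes, not errors. Interpolation is
total: a single-anchor chromosome extrapolates at the fallback rate around
its anchor. Problem sizes in the test-bed (100 replicates for recovery,
500 offspring for the inbreeding coefficient, 1,000 random strings and
1,000 exclusion configurations for oracle equivalence) were chosen so the
Monte-Carlo standard errors are small relative to the quantities checked
while the whole suite stays desk-scale.

## Known limitations

The affected-sharing surrogate cannot separate IBD from long
identity-by-state runs; with real LD the genetic-length filter carries more
of that burden. X-chromosome inheritance is treated as autosomal (or the
chromosome can be excluded upstream). Compound heterozygosity, reduced
penetrance, phasing and imputation are out of scope, as are
deleteriousness predictions — those arrive, if at all, as input columns.
The table-driven prioritization trusts its input's zygosity and frequency
annotations; no database lookups are performed.
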