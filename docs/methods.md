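# Methods

## Scope and data model

The package operates on biallelic SNP/Indel genotype matrices
(accessions × markers, alt-allele dosage 0/1/2 with explicit missing
calls), the data regime of reduced-representation sequencing (RADseq/GBS)
in ornamental tree germplasm. Markers carry contig + 1-based position; all
windowed operations use 0-based half-open bins anchored at position 0 of
each contig, so bin membership is `(position − 1) // window`. Multi-allelic
records are skipped on VCF import (counted, not silently dropped);
phasing, imputation, and variant calling are out of scope.

## Marker filtering

The filter cascade retains markers with MAF ≥ 0.05 (allele-count
definition over non-missing calls), missingness ≤ 0.10 (over all
accessions), and heterozygote frequency ≤ 0.90 (over non-missing calls —
the denominator convention is ours; the criteria are conjunctive, hence
order-free and idempotent). Window thinning keeps one marker per 500-bp
bin by highest heterozygosity (ties: lower missingness, then smaller
position). LD pruning is a deterministic greedy pass: within 100-marker
sliding windows (step 10), any dosage pair with squared Pearson
correlation > 0.5 (pairwise-complete; zero-variance pairs count as r² = 0)
loses the member with more missing data (tie: later position), repeated
until a full pass removes nothing. Markers on different contigs are never
pruned against each other. Random thinning to a target count is a uniform
sample without replacement under an explicit seed.

## Clonal identity

The modified Gower similarity scores each jointly-genotyped locus 1 / 0.5
/ 0 for identical / one-shared-allele / opposite-homozygote genotypes; in
dosage coding `s = 1 − |x − y|/2`, which the pairwise implementation
evaluates by indicator-matrix products (an oracle test checks it against a
naive per-locus loop). Pairs sharing fewer than `min_overlap` (default
100) genotyped loci are flagged undefined rather than given a misleading
value. Clone groups are connected components of the GS > 0.995 graph
(single linkage): near-identical triplets observed in practice are joined
through intermediates, and any within-group pair at or below the threshold
is logged. Each group gets a representative (lowest missing rate, then
lexicographic id) for de-duplicated downstream analyses. The theoretical
self-progeny similarity is `1 − h/4`: a heterozygous locus segregates
1/4 : 1/2 : 1/4 in a self, and the homozygous outcomes score 0.5 against
the parent, so each contributes 0.75 in expectation. Genotyping error of
rate *e* pulls clone-pair GS to ≈ 1 − e, hence the 0.995 threshold
comfortably separates clones (e ≈ 0.003 → GS ≈ 0.997) from even the
closest relatives.

## Parentage

**Dyads.** P_OHL is the fraction of jointly-genotyped loci in opposite
homozygous states. Eligible pairs must join a parent-capable and an
offspring-capable accession (roles parent/offspring/all); pairs inside a
supplied clone group are excluded, since a clone has P_OHL ≈ 0 without
being a parent. **Triads.** For each candidate parent pair, the expected
progeny genotype is defined at loci homozygous in both parents
((0,0)→0, (2,2)→2, (0,2)→1) and the Gower dissimilarity GD = 1 − GS
between EP and each candidate offspring (restricted to EP loci genotyped
in the offspring, minimum 100) is pooled across all parent pairs.

**Significance.** Values are sorted ascending; consecutive gaps computed;
the largest gap among the first ⌊n/2⌋ gaps (earliest index on ties) is
tested as a high outlier against 29 gaps sampled uniformly without
replacement from all remaining gaps. The outlier statistic is Dixon's r22
ratio on the pooled sample of 30 (numerator skips two ranks at the tested
end, denominator two at the opposite end); p-values are Monte-Carlo
estimated under a standard-normal null (100,000 replicates, cached and
seeded — published critical tables are sparse at n = 30 and the MC version
gives continuous, reproducible p-values). If the gap is significant at α,
every candidate below it is tested as a low outlier against the 29 lowest
candidates above the gap; those with p < α are reported significant.
Orientation (which member is the parent) comes from date metadata when
available, else from asymmetric roles. No multiple-testing correction is
applied by default. The literature rule-of-thumb P_OHL ≤ 0.010 for true
dyads is exported as a constant for reporting but never drives
significance.

**Known limitation — the first gap test is anti-conservative on null
data.** On a fully unrelated population the ordered P_OHL values form a
smooth cloud, and the *maximum* of ~10³ order-statistic spacings is
structurally far larger than typical spacings, so testing it against 29
randomly sampled gaps flags a "significant" gap on most null datasets.
The procedure's protection against false parentage calls comes from the
second stage: the candidates below such an artifactual gap are not extreme
relative to the 29 values just above it, so they come out non-significant
and the scan returns no false dyads. Interpret the gap-test p-value as a
screen, not as evidence that true dyads exist. A separate structure
warning fires when more than 25% of pairs fall below P_OHL 0.02 — the
signature of strongly differentiated subpopulations (e.g. the two *C.
kousa* subspecies) depressing the statistic, which can mask or fake the
gap.

## Interspecific composition

Species-diagnostic markers are selected from reference accessions of each
species: pooled reference call rate ≥ 0.88 (the pooled reading of the
presence criterion; a per-group variant would be stricter), every
non-missing reference call homozygous, each group internally fixed, and
groups not all fixed for the same allele. With ≥ 3 groups a marker belongs
to the unique odd-group-out; with exactly 2 groups it is assigned to the
group fixed for the rarer pooled allele (ties: lexicographically smaller
label). Panels are equalized to the smallest panel's size by first capping
markers per 500-bp bin at 3 (keeping the highest call rate, and never
dropping below the target), then removing the lowest-call-rate markers
(ties: later position).

Composition scores each panel locus L = 1 / 0.5 / 0 (homozygous species
allele / het / other-or-missing) and normalizes the per-species sums to
percentages. Scoring missing data as 0 follows the assay convention this
reproduces; it deflates the numerator for high-missingness accessions, so
a per-accession call-rate column is emitted to make the bias visible.
Accessions with zero total signal are flagged undefined rather than
divided by zero.

Introgression segments are maximal runs of consecutive panel loci (per
donor panel, per contig, position-ordered) with L ≥ 0.5; runs of ≥ 3 loci
become segments (span = positions of the flanking supporting loci, an
inner-span lower bound), shorter runs are reported as singleton putative
genotyping errors — isolated single donor alleles are deliberately not
called introgressions. A missing call inside a true block scores L = 0 and
splits the run; segment calling is therefore best done on high-call-rate
data. Coverage-gap accounting bins inter-locus distances per contig
(default 3–5 Mb and ≥ 5 Mb) to show where introgressions could hide.

Pedigree-expected composition evaluates a DAG of founders, crosses,
selfs, open-pollination (OP) events, clones, and apomicts: a cross
averages its parents' species vectors; self/clone/apomict copy the parent;
an OP node averages the mother with the pure vector of the assumed pollen
species (a required assumption, defaulting to the recurrent species of the
breeding program). This yields the textbook halving series: F1 50%, BC1
25%, BC2 12.5%, BC3 6.25% donor. Triploids are not representable.

## Subspecies panel

Fixed-difference markers between the two *C. kousa* subspecies are
selected from reference sets (all non-missing chinensis reference calls
homozygous for one allele, all kousa reference calls for the other),
ranked by pooled call rate; the top 7 form the default assay panel.
Accessions are scored 0 / 0.5 / 1 per marker (chinensis-hom / het /
kousa-hom); the mean over non-missing markers classifies: < 0.10
chinensis, > 0.90 kousa, otherwise hybrid, with the boundary values
falling in the hybrid band (configurable). Unlike composition's L rule,
missing calls are excluded from the mean — the physical assay this mimics
produces no missing-as-zero reads. The full diagnostic set scored the same
way serves as the membership proxy that panel classifications are judged
against (concordance fraction plus a per-accession disagreement table).

## Synthetic data generator

Founder pools (default 10 *C. florida*, 10+10 *C. kousa*
chinensis/kousa, 6 *C. nuttallii*) are simulated over 10 contigs of 10 Mb
with 300 markers each: species-diagnostic loci fixed homozygous for the
species allele in the owning species and for the alternative elsewhere;
subspecies-diagnostic loci separating the two kousa pools (which otherwise
share background allele frequencies); background loci with per-species
frequencies from Beta(0.8, 0.8) (a U-shaped law giving many near-fixed and
some common variants, qualitatively like reduced-representation SNP
discovery) and Hardy–Weinberg founders. Meiosis draws Poisson(1.5)
crossovers per contig at uniform positions, without interference or
obligate chiasma — adequate for segment-scale questions, not for fine
interference statistics. Pedigree evaluation supports cross, self, OP
(gamete × random founder of the assumed pollen pool), clone, and apomict
nodes; phase and per-haplotype founder-species labels are tracked
internally (public outputs are unphased) so realized ancestry fractions,
donor block boundaries, and clone groups are exact by construction.

The error model sets each call missing with probability m = 0.02, else
miscalls it with probability e = 0.003 — heterozygotes to a random
homozygote, homozygotes only to heterozygotes. The direction asymmetry is
deliberate: a single miscall can then never produce an opposite-homozygote
parent–offspring locus, which reproduces the empirical per-mille scale of
true-dyad P_OHL and true-clone GS of 0.996–0.999. No published error-rate
estimate exists for this regime, so both rates are configurable; they were
chosen once to match those reported scales. What the generator does *not*
emulate: linkage disequilibrium within founder pools, allele-frequency
correlation between species, locus dropout correlated with divergence
(null alleles), triploidy, and selection against hybrid gametes — so
passing benchmarks demonstrate correctness of the statistics under clean
Mendelian structure, not robustness to every real-data pathology.

## Benchmark problem sizes

The standard regimes used by the test suite and `scripts/acceptance.py`:
within-species scans use 3000 background markers (60 unrelated accessions
+ 10 planted dyads or trios; 20 seeded replicates, medians reported);
clone detection uses 200 clone pairs at 3000 markers (grouping rate as a
median over 5 seeded replicates, since single draws of a ~0.3% per-pair
failure rate are noisy); composition recovery uses ~2703 diagnostic loci
per species with 26 reference accessions and 50 BC2 individuals; segment
agreement uses 900 loci/species error-free (a genotyping error inside a
donor block would legitimately split a called segment, so the
truth-agreement check isolates the caller from the error model); the
subspecies benchmark uses 300 planted fixed differences and 60 accessions.
These sizes mirror the marker counts the analyses are designed for while
keeping a full run in minutes on one CPU.
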