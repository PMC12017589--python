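# Methods

This note documents the models and procedures implemented in `pigpan`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that matter when comparing
output against other tools.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to and from
1-based inclusive conventions (VCF, GFF3, 12-column tabular search hits)
happens only in `pigpan.io`. SV VCFs encode PAV absences as `DEL` (with
`END` only — htslib reinterprets the span when `SVLEN` accompanies `END` on
symbolic alleles), presences as `INS` with `SVLEN` and optionally the inserted
sequence, inversions as `INV`, and translocations as `BND` mate pairs joined
by `MATEID`. Genotypes are biallelic dosages 0/1/2 with missing as NaN;
multi-allelic records are split into one biallelic record per alternate
allele at read time, since every downstream statistic assumes biallelic
dosage.

## Gene-family occupancy

Families are classified by the number of carrier genomes against explicit
absolute-count bands; the gene default at *n* genomes is core = *n*,
softcore = [*n*−2, *n*−1], dispensable = [2, *n*−3], private = 1. Bands are
parameters rather than fractions because the gene and SV classifications use
different softcore rules (the SV rule is share > 0.9 but not all). Summary
percentages are rounded half-up to two decimals, matching how such tables
are printed; this matters only at exact .5 ties where banker's rounding
would disagree. Accumulation curves average pan (families in ≥ 1 of the
first *k* genomes) and core (families in all *k*) sizes over seeded random
genome orderings; 100 permutations by default. Exhaustive enumeration is
used as the test oracle at 3 genomes.

## Non-redundant SV merging

Genomes are merged in their given order. A call is redundant with an
existing record when both have the same type and chromosome and either
(span types: absence, inversion) the reciprocal overlap — the smaller of the
two mutual overlap fractions — is ≥ 0.5, or (point types: insertions and
translocation breakends) the breakpoints lie within 100 bp and the length
ratio is ≥ the same threshold, with translocation mates required to agree in
chromosome and position window. First-seen coordinates are kept; no
consensus averaging. The 0.5 / 100-bp defaults are the field's common
merging parameters and are exposed as arguments. Growth (catalogue size)
and shared (records carried by every genome so far) curves are recorded
after each genome; the first is non-decreasing and the second
non-increasing by construction. Repeat filtering removes records whose
span is *strictly more than* 90% covered by a supplied repeat track; the
fraction is computed as intersected bp over SV length against the merged
repeat footprint.

## Hotspots

SV breakpoints — both interval ends, plus the mate breakend for
translocations — are counted in 200-kb windows with 100-kb step; a
breakpoint falling in several overlapping windows is counted in each.
Windows are ranked genome-wide and the threshold is the value of the
ceil(0.05 × *n*)-th window in descending order; ties at the threshold are
included but zero-count windows never qualify (a hotspot must contain at
least one breakpoint). Overlapping or abutting hotspot windows merge into
hotspot regions; with step < window, neighbours overlap, so "consecutive"
means interval-adjacent. Per-population hotspots restrict the presence
matrix to the population's genomes before windowing.

## Windowed population genetics

- π: per-site mean pairwise difference 2*p̂*(1−*p̂*)·*n*/(*n*−1) from allele
  counts with missing-aware denominators, summed over a window and divided
  by the window span in bp (the convention of windowed-π tools).
- Ts/Tv: transition site count over transversion site count per window;
  undefined (NaN) without transversions.
- Tajima's *D*: the standard 1989 formulation from the window's segregating
  sites and total pairwise diversity; undefined when *S* = 0. With missing
  data the sample size is the modal called-chromosome count over the
  window's segregating sites — adequate because QC caps missingness at 5%.
  The test oracle is a constructed window (n = 4 chromosomes, 8 singletons +
  3 doubletons) where pairwise diversity equals Watterson's estimator
  exactly, forcing *D* = 0.
- *F*<sub>ST</sub>: Weir–Cockerham (1984) variance components *a*, *b*, *c*
  per site from diploid dosages (dosage 1 = heterozygote), window value
  Σ*a* / Σ(*a*+*b*+*c*). Negative estimates are reported, not clipped; they
  are informative under the null and do not affect top-quantile selection.
- QC: a variant is removed when mean depth < 5, missing fraction > 0.05, or
  MAF < 0.1. The missingness rule is deliberately a call-rate reading
  (> 5% missing removed): the literal alternative ("remove when > 95%
  missing") would remove almost nothing and could not produce the heavily
  reduced marker sets such a filter is meant to yield; the threshold is a
  parameter, so the literal behaviour is available as `max_missing=0.95`.
- LD pruning follows PLINK `--indep-pairwise 50 10 0.1`: within a 50-variant
  window every pair with *r*² above threshold drops the later variant, then
  the window slides by 10. Deterministic by construction.

## V_ST selection scan

*V*<sub>ST</sub> = (*V*<sub>T</sub> − *V*<sub>S</sub>)/*V*<sub>T</sub> with
variances computed with denominator *n* (the population-variance form used
throughout the V<sub>ST</sub> literature; `ddof` is a flag) and
*V*<sub>S</sub> the within-population variances weighted by non-missing
population sizes. *V*<sub>T</sub> = 0 makes the statistic undefined and the
locus is excluded from ranking. Finite-sample noise can push
*V*<sub>S</sub> above *V*<sub>T</sub>; the reported value is floored at 0
with the raw value retained for diagnostics. The top-1% rule ranks defined
values descending, thresholds at rank ceil(0.01 × *n*<sub>defined</sub>),
and includes ties.

Sweep regions intersect the top-5% windows of *F*<sub>ST</sub> with the
top-5% windows of the π ratio (population 1 over population 2, supplied in
that order so diversity loss in population 2 raises the ratio). The
intersection is the stricter reading of requiring both signals; windows with
an undefined ratio (zero denominator) are excluded from ranking.

The SV–sweep overlap test permutes SV *identity*, not position: the null
redraws |selected| SVs uniformly without replacement from the catalogue and
recounts sweep overlaps, preserving the chromosome and length composition of
the background. The empirical p is (1 + #{null ≥ obs})/(*n*<sub>perm</sub> + 1),
which is valid (never anti-conservative) but, on a discrete overlap count,
slightly conservative: ties between null draws and the observed count shift
its mean above 0.5 by about half the tie probability. Calibration
experiments therefore use catalogue/selection sizes large enough (hundreds
of expected overlaps) that the count is fine-grained and the
Kolmogorov–Smirnov check against uniformity is not confounded by
discreteness.

## Feature enrichment

The null re-places each SV uniformly at random on its own chromosome,
preserving length, with no overlap constraint — the standard positional
null for interval enrichment. The overlap unit is the SV count at ≥ 1 bp
intersection (matching statements about SVs as units being depleted in
genic regions); fold = observed / mean(null), two-sided empirical
p = (1 + #{|null − mean| ≥ |obs − mean|})/(*n*<sub>perm</sub> + 1), direction
by the sign of obs − mean. Strata (by SV type, or by population-origin
category) reuse the same permutations. When promoters are not annotated
they are derived as strand-aware 2-kb windows upstream of each gene start
(a conventional promoter definition; the window is a parameter), and
introns as intra-gene gaps between exons.

## Mechanism inference

The cascade is, in order: tandem-repeat coverage of the span ≥ 0.8 → VNTR;
transposable-element coverage ≥ 0.8 with one distinct family → STEI, with
two or more → MTEI; junction homology ≥ 50 bp at ≥ 90% identity → NAHR;
otherwise → NHR; records without sequence are unassigned. Thresholds
(coverage 0.8, homology 50 bp, identity 0.9, flank 500 bp) reconstruct the
conventional breakpoint-junction workflow for large SV sets and are all
configurable. Homology search is exact-seed extension along diagonals with
mismatch-tolerant outward extension — deterministic, gap-free, and
sufficient at the 50-bp calling scale; it is not a full local aligner. The
junction windows take 500 bp of flank plus at most half the SV sequence on
each side, so the two junctions never share SV bases (self-overlap would
fabricate homology for SVs shorter than twice the flank). Mechanism
proportions are reported over assigned calls with the assignment rate given
separately.

## NUMT catalogue and dating

Search hits of a doubled (twice-concatenated) mtDNA against each assembly
are unwrapped modulo the circle length, with junction-spanning hits kept as
a two-interval pair. Nuclear-adjacent hits within 1 kb merge into per-
assembly NUMTs; across assemblies, NUMTs cluster when their nuclear
positions agree within a 1-kb anchor window and their mt intervals overlap
(assemblies are assumed to share the reference coordinate frame — the
simulation writes them that way; for real assemblies a lift-over or
flanking-anchor step would precede this). Frequency classes: private
(exactly one assembly — precedence), common (*F* ≥ 0.1), rare (the rest).
With 19 assemblies a presence of 2 already gives *F* ≈ 0.105, so a literal
*F* < 0.1 rare band is nearly empty; both the threshold and the denominator
are parameters rather than hard-coded.

Dating: at aligned positions where modern and outgroup mtDNA differ
(diagnostic sites), the fraction *m*/*d* of sites where the NUMT carries
the modern allele estimates the fraction of modern-lineage mutations that
predate the insertion, so age = *T*<sub>div</sub> × (1 − *m*/*d*) with
*T*<sub>div</sub> = 9.7 MY. All-modern NUMTs date to 0 (recent insertion),
all-ancestral to *T*<sub>div</sub>. Sites where the NUMT matches neither
allele (triallelic) are excluded; *d* = 0 leaves the age undefined. Aging
is restricted to records of 50–1000 bp, the band where a single gapless
alignment segment is a reasonable assumption. Under the clock the
binomial sampling of *m* gives an unbiased estimator with standard error
*T*<sub>div</sub>·√(*q*(1−*q*)/*d*), about 0.6 MY at *d* ≈ 60 — the basis of
the ±1 MY recovery check.

## Synthetic data

Generators are pure functions of their arguments including the seed, and
every emitted object appears in the returned truth table.

- Occupancy: class counts by largest-remainder apportionment of the mix
  (default 47/18/34/1% core/softcore/dispensable/private, the observed
  shape of real gene-family tables); occupancy drawn uniformly within the
  class band, carriers uniformly.
- SV call sets: a pool of redundancy groups; a group is shared (2..n
  carriers) with the redundancy probability, otherwise private. Carriers'
  calls jitter both breakpoints together by ≤ 10 bp — small against the 50%
  reciprocal-overlap rule, so planted groups always merge. Same-type groups
  are placed disjointly (point types at least 200 bp + 2×jitter apart) so
  each group remains a distinguishable catalogue record and the truth table
  is a valid merge oracle at any seed. Default per-genome rates total
  2,000 SVs across a 60-Mb three-chromosome toy genome — the study-scale
  ratio of PAVs to inversions to translocations with log-normal length
  modes at 1.5 kb (PAV), 15 kb (inversion) and 2.5 kb (translocation),
  matching the 1–2 kb / 10–20 kb / 2–3 kb modes reported for real
  catalogues, at a desk-scale count.
- Genotypes: Hardy–Weinberg binomial(2, *p*) dosages. Undifferentiated loci
  share one frequency (uniform on [0.05, 0.95]); differentiated loci have
  frequencies separated by the divergence gap with the high population
  randomised. HW is the minimal neutral genotype model; nothing in the
  statistics under test depends on LD structure, which is not simulated.
- NUMT landscape: mutations are placed on the modern mt lineage uniformly
  in time over 9.7 MY (molecular clock — the same linear-accumulation
  assumption the age formula makes) at 0.01 substitutions/site/MY, chosen
  so that 50–1000-bp NUMTs carry ≥ 30 diagnostic sites (the same order of
  magnitude as Suinae mitochondrial divergence, raised enough to make
  per-NUMT dating informative at desk scale). The outgroup carries the
  ancestral allele at every mutated site; a NUMT of age *a* copies the mt
  state at that age. Assemblies share one nuclear backbone with NUMTs
  substituted at fixed positions, so cross-assembly clustering is exact by
  construction.
- Features: a deterministic gene grid (5-kb genes every 50 kb, three exons,
  2-kb promoters, intergenic enhancers) with SVs placed by rejection
  sampling on the planted per-class multiplier, so the accepted density of
  SVs overlapping a class is multiplier × background in exactly the units
  the enrichment test counts.

What passing on synthetic data does not show: real SV call sets have
alignment-driven breakpoint uncertainty far above 10 bp in repeats, real
genotypes have LD and population structure beyond two clean demes, real
NUMT alignments have indels and require a real aligner, and real feature
annotations overlap in ways the toy gene grid does not. The tests validate
the implementations' logic and calibration, not caller accuracy on real
genomes.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen so each statistical band sits
several standard deviations from its threshold under the generator's noise
model: 10,000 loci / 2 × 50 individuals for the scan-sensitivity check,
200 NUMTs with *d* ≥ 47 for age recovery, 6,000 SVs (planted) and 20,000
SVs (null) for the enrichment folds, and 200 calibration simulations × 1,000
permutations for p-value uniformity. All randomised code paths take an
explicit seed; `scripts/acceptance.py` derives per-experiment seeds from its
single `--seed` via `numpy.random.SeedSequence`.
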