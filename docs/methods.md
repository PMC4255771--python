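# Methods

## Data model

A locus is a self-contained multiple alignment of phased haplotypes over
{A,C,G,T,-}, with strain and population identity parsed from FASTA headers
(`strain|population`) and at most one designated outgroup sequence.
Coordinates are 0-based half-open internally and 1-based inclusive in report
tables. The hairpin annotation places the hairpin, miR, miR* and loop
intervals in locus coordinates; the seed defaults to miR positions 2–8
(the 7-nt convention of seed-based target prediction), measured from the miR
5' end, so on minus-strand loci it sits at the right edge of the stored miR
interval. Loci are oriented before analysis so the miR reads 5'→3' left to
right; orientation reverse-complements sequences (gaps preserved) and flips
intervals by `new_start = L − old_end`. The strand field records genomic
strand and is not rewritten, which makes orientation involutive; the
pipeline applies it exactly once.

Heterozygous input is rejected rather than resolved: the package expects
phased haplotypes, and IUPAC ambiguity codes are treated as alphabet errors.

## Gap and site conventions

Columns with a gap in any ingroup haplotype are excluded from SNP calling,
diversity, and the surveyed length L (complete deletion), making L
unambiguous across statistics. Gap runs are scored separately as indel
events: one event per maximal run of consecutive gap columns with an
identical carrier set, with overlap flags against the annotated intervals
and the fraction of the hairpin removed. Multiallelic columns count as one
segregating site and contribute to π through the heterozygosity form, but
are excluded from the folded/unfolded spectra used by the SFS tests. A site
polarizes only when the outgroup base is gap-free and matches one observed
ingroup allele; polarization failures stay in folded/minor-allele analyses
and drop out of the unfolded SFS and Fay–Wu H. Pairwise operations
(Jukes–Cantor, F_ST) use pairwise deletion over the two sequences compared.

## Statistics

- π is computed per gap-free column as (n/(n−1))(1 − Σ_b p_b²) and summed;
  this equals the all-pairs mean difference exactly (the unit tests enforce
  agreement with a brute-force all-pairs oracle to 1e−12).
- θ_W = S / a_n / L with a_n = Σ_{i=1}^{n−1} 1/i.
- SNP density = (S/L)/ln(n−1); natural log, chosen because the correction is
  of the Watterson type (a_n ≈ ln n); undefined at n ≤ 2 and reported as NA.
- Tajima's D uses the 1989 constants (a₁,a₂,b₁,b₂,c₁,c₂,e₁,e₂) computed from
  n; undefined (NA, never 0) when S = 0 or n < 4.
- Normalized Fay–Wu H = (θ_π − θ_L)/√Var with θ_π = Σ 2i(n−i)S_i/(n(n−1)),
  θ_L = Σ iS_i/(n−1) and the variance of Zeng, Fu, Shi & Wu (2006),
  Var = (n−2)/(6(n−1))·θ̂ + [18n²(3n+2)b_{n+1} − (88n³+9n²−13n+6)]
  /(9n(n−1)²)·θ̂², with θ̂ = S/a_n and the unbiased θ̂² = S(S−1)/(a_n²+b_n),
  b_n = Σ_{i<n} 1/i². The neutral calibration tests (mean ≈ 0, SD ≈ 1 over
  5,000 conditioned replicates) double-check the variance implementation.
- Jukes–Cantor K = −(3/4)ln(1 − 4p/3); p ≥ 3/4 raises a saturation error.
  The representative ingroup allele defaults to the first haplotype and is
  selectable, mirroring reference-strain conventions with fallback order.
- F_ST is Hudson's 1 − H_w/H_b: H_w averages the within-population pairwise
  difference rates with equal population weight; H_b averages the
  between-population rates with equal population-pair weight. Negative
  estimates are reported, not clamped; H_b = 0 yields NA. Note the exact
  finite-sample property that duplicating a population gives −1/(n−1)
  (the between-population mean includes the diagonal identical pairs), which
  vanishes only as n grows. A haploid ANOVA (variance-components) estimator
  is available behind `estimator="variance_components"`.
- Benjamini–Hochberg step-up adjustment is applied across loci at q = 0.05,
  separately for the D and H families.

## Coalescent nulls

Genealogies follow the standard neutral (Kingman) coalescent: with k
lineages the waiting time is Exp(k(k−1)/2) in units of 2N generations and
merging pairs are uniform; no recombination within a locus and no demography
in the null. Mutations are infinite-sites, placed on branches with
probability proportional to branch length. Null distributions for D and H
are conditioned on the observed S (the convention of the simulation programs
this emulates; a θ-conditioned mode exists via `drop_mutations_theta`), with
defaults of 50,000 replicates for D and 10,000 for H. Empirical p-values use
the add-one estimator, flooring p at 1/(replicates+1); D is two-tailed
(2·min(lower, upper) capped at 1 — the tail convention is a package choice),
H lower-tailed. Because D and H are discrete at small S, tie counting uses a
1e−9 relative tolerance so scalar- and vector-computed statistic values
compare equal; without it, ties between an observed value and its identical
null atoms can be missed and p-values collapse spuriously.

Large null samples are drawn by a vectorized sampler over branch-size
segments (the derived count of a mutation is the descendant count of the
segment it lands on); unit tests verify it is distributionally identical to
the explicit-genealogy path and cross-check total branch length against
msprime. Within a pipeline run, nulls are cached by (statistic, n, S,
replicates).

## Synthetic data generator

The generator emulates the sampling design the analysis targets, and its
defaults are the study conditions used throughout the tests:

- 129 loci of 479 bp: 200 bp flanks around a 79 bp hairpin
  (10 backbone + 22 miR + 15 loop + 22 miR* + 10 backbone).
- Three populations sampled at 10/9/10 haplotypes (sample-size medians of
  the motivating survey), merging backward in time into one ancestral pool
  at 0.2 and 0.4 coalescent units. One genealogy per locus spans all
  populations: complete linkage, no migration after splits.
- θ_flank = 0.04 per site, the neutral diversity of the motivating system
  (~4% of sites differing between two alleles absent constraint).
- Purifying selection is emulated by rate-thinning: per-domain multipliers
  on the flank rate (miR 0.05, miR* 0.1, backbone 0.3, loop 0.6, flank 1.0),
  chosen to mirror the observed ~20-fold miR suppression. This reproduces
  the diversity-suppression signature while keeping every rate analytically
  checkable (realized per-domain mutation counts are recorded in the truth
  table and χ²-tested against the configured rates); it is not a fitness
  model and produces no selective SFS distortion. Skewed spectra for
  exercising the D/H machinery are available via an explicit external-branch
  placement bias, documented as a caricature.
- The outgroup descends from the ingroup root with Poisson(0.04 × domain
  multiplier) substitutions per site — constraint acts on the outgroup
  lineage too. Measured K therefore exceeds the branch parameter by the
  ingroup root-to-leaf mutation contribution (≈ θ per site at neutral
  sites); tests assert against this model expectation, not the raw
  parameter. Outgroup substitutions can hit polymorphic columns, so
  polarization failures arise naturally.
- Mutations are applied per column, oldest first, each changing the current
  base to a uniform alternative; multiple hits (and hence triallelic sites
  and slight saturation at θ = 0.04) occur naturally. Expression read counts
  are lognormal with a higher location for seed-conserved loci; ~74% of loci
  carry a conserved seed family and ~74% lie >200 bp from their nearest
  neighbour, matching the proportions the windowing filter expects.
- Injected events: a seed SNP or a deletion carried by ⌈freq·n_pop⌉
  haplotypes of one population (deletion default: 14 bp spanning the seed).
- Determinism: each locus is generated from `default_rng([seed, index])`, so
  datasets are byte-identical across runs and independent of generation
  order.

What the generator does not emulate: real base composition and mutation
spectra, indel polymorphism arising from the coalescent itself (indels exist
only as injected events), recombination, migration, demographic
non-equilibrium, alignment error, and any direct coupling between expression
and diversity beyond the conservation-class offsets. Passing tests therefore
demonstrate correctness of the estimators and the stated selective-signature
recovery, not robustness to those real-data complications.

## Windows, filters, classification

Sliding windows (15 bp, step 5) are computed per locus on a grid aligned to
the first miR position, each window using its own gap-free length; rows are
cross-locus means per relative start, retained only when ≥10 loci contribute
(the "point estimate" is the per-position cross-locus mean, so the ≥10 rule
applies to contributing loci per position). Loci within 200 bp of another
miRNA are excluded so flanks are miRNA-free. The misannotation filter flags
a locus when hairpin π strictly exceeds flank π; loci without usable flanks
are marked not-evaluable. Conservation is classified from the seed-family
presence set: strict (unique iff no other species shares the family) and
relaxed (low iff at most one does). Flank summaries pool both sides
length-weighted; per-side views are also emitted. The "backbone" summary
follows the reporting convention hairpin − miR; the finer residual is
emitted as `backbone_strict`.

## Pipeline and reporting

Stages run read → orient → scan/polarize → partition → summaries →
neutrality (hairpin SFS, reference population sample, default "OH") → BH →
F_ST → windows → classification → flags → report. Loci that fail a stage are
logged to an exclusions table so every manifest locus is accounted for.
Group contrasts (diversity and expression between conservation classes,
expression–diversity rank correlation) use Wilcoxon–Mann–Whitney and
Spearman tests from scipy. All randomness flows from one seed; every table
carries a JSON metadata header (seed, replicate counts, version, config
hash). Outputs are TSV; an optional minimal VCF export of variants was
considered and dropped as out of scope for the report bundle.

## Problem sizes and tolerances

The default test and acceptance runs use the full 129-locus design for
parameter recovery (20 seeds), 50,000-replicate D nulls with 2,000 neutral
pseudo-observations for calibration (rejection rate within [3.5%, 6.5%] at
nominal 5%), 5,000–10,000 replicates for H calibration and the coalescent
identities (3-SE bands), and 500 random alignments for the π oracle at
1e−12. Statistical tests in the suite are seeded and deterministic.

## Known limitations

- The null assumes panmixia within the tested sample; testing a pooled
  structured sample against it would be anticonservative (the pipeline
  therefore tests within the reference population).
- Fay–Wu H requires polarizable sites; loci without an outgroup or with
  systematic polarization failure silently contribute only to folded
  analyses, mirroring the sparsity of H results in real surveys.
- Jukes–Cantor saturates at p ≥ 0.75 and is the only divergence model
  offered.
- The misannotation filter is a point comparison without uncertainty; it is
  conservative by design and may flag true miRNAs under adaptive evolution.
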