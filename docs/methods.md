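# Methods

This note documents the models, the defaults, and the deliberate
simplifications behind `strainpop`, roughly in pipeline order.

## Input model

The package starts from genomes already laid out in reference coordinates
(one equal-length record per strain plus the reference): whole-genome
alignment is upstream of this package, as are assembly, annotation, and
pan-genome construction (consumed as an Rtab presence/absence matrix plus a
gene → COG/KEGG annotation table).  All internal coordinates are 1-based
inclusive; BED's 0-based half-open convention is applied only at the
reader/writer boundary.

## Core SNPs and distances

A column is *core* when the fraction of strains with an unambiguous base is
at least `core_fraction` (default 1.0, the strict core; exposed because the
core is meant to be rebuilt per strain subset).  Among core columns, those
with exactly two observed bases (reference included) become sites; columns
with three or more bases are dropped.  Distances use pairwise deletion of
missing calls and are reported as absolute SNP counts, not rates, because
every downstream threshold (300 for clonal pruning, 2500 for semi-clonal
groups, 10 for clonal groups) is an absolute count.  Whether sites absent
from a pair's shared core should be counted differently is not decidable
from counts alone; pairwise deletion is the documented choice here.

Neighbor joining is the Saitou–Nei algorithm with the Studier–Keppler Q
criterion; ties in Q are broken by lexicographic pair order so the result
is deterministic, and negative branch estimates are clamped to zero with
the deficit shifted to the sibling so path lengths of additive matrices are
reproduced exactly (verified to 1e-9 in tests).

## Population structure

**Clonal pruning.** Single-linkage components of the graph {d < 300} are
collapsed to one representative chosen uniformly at random under the run
seed.  Single linkage is used because a "less than threshold" grouping rule
is transitive by construction.

**Painting.** The co-ancestry matrix is built by a per-window
nearest-donor rule: the SNP matrix is cut into consecutive windows of 100
columns (a trailing window at least half-sized is kept, otherwise merged),
and for each recipient and window the non-self donor(s) at minimal Hamming
distance share one chunk equally.  This is a deliberate simplification of
the ChromoPainter/fineSTRUCTURE HMM+MCMC machinery: under a uniform
recombination rate the window-local nearest donor carries the dominant
copying signal, and the rule is deterministic, mass-conserving (every row
sums to the window count, ties split evenly), and exactly testable.  It
does not model linkage within windows, donor switching costs, or
uncertainty in donor choice.

**Clustering.** Row-normalized co-ancestry profiles are clustered by
average-linkage hierarchical clustering (Euclidean); K maximizes the mean
silhouette over K = 2…10 (smallest K on ties).  A best silhouette below
0.25 flags "weak structure".  An MCMC cluster sampler would additionally
give assignment uncertainties; the deterministic stand-in gives none.
Clusters smaller than `min_size = 4` are treated as residual clonal signal
(such groups typically comprise two or three strains): all but one random
member are dropped and painting + clustering repeat on the reduced set.

**Fst.** The haploid Weir–Cockerham estimator: per locus a one-way ANOVA
on allele indicators with MSP, MSG and n_c as usual, a = (MSP − MSG)/n_c,
b = MSG, and multi-locus θ = Σa / Σ(a+b); monomorphic loci contribute 0/0
and are skipped, and populations with fewer than two members are excluded.
θ is invariant to a global allele-label swap and equals 1 for fixed
differences.

## Association

Population scans are one-vs-rest two-sided Fisher exact tests with **no**
structure correction — deliberate, since the scan looks for the variants
that define the populations themselves.  With a binary phenotype, binary
genotypes and no covariates the exact test is the natural fixed-effect
test, and it is implemented by integer hypergeometric enumeration (exact
tie handling, no float tolerance), so tests can demand agreement with a
brute-force oracle to 1e-12.  Carriage filters are exclusive bounds:
5–95 % for population scans, 1–99 % for phenotype GWAS.  Enrichment uses
the one-sided (greater) Fisher test per COG/KEGG term against the
reference-genome background with threshold α/n_terms = 0.01/220.

Phenotype GWAS is a fixed-effect model: continuous phenotypes by OLS
(vectorized via Frisch–Waugh residualization; numerically identical to
per-variant least squares, asserted against statsmodels in tests), binary
phenotypes by logistic regression with a Firth-penalized fallback on
separation.  Structure covariates are classical (Torgerson) MDS axes of a
MinHash sketch distance matrix, d = −(1/k)·ln(2j/(1+j)) with k = 21 and
sketch size 1000 by default (standard sketching defaults; the retention
rule — smallest number of positive-eigenvalue axes reaching 80 % of the
positive eigenvalue mass, capped at 10 — is this package's choice).
Missing phenotypes are dropped casewise per phenotype.  SNP-based and
gene-based scans form separate Bonferroni families.

## Transmission

Semi-clonal groups (SCGs) are single-linkage components at d < 2500 with
SNPs re-called on each group's own core (the core grows as the strain set
shrinks).  Recombination masking is a windowed Poisson outlier scan
against the group consensus, standing in for a branch-wise recombination
model: per strain, windows of 1000 bp anchored at every
strain-vs-consensus difference (in both directions) are flagged when their
difference count exceeds the Poisson(strain-wide rate × window) upper tail
at 1e-4.  Every difference inside a merged flagged interval is masked, but
the masked *intervals* are the spans of difference runs split at gaps
larger than max(5 × median in-interval gap, 50 bp) — so isolated
background differences caught in a flagged window's reach become point
masks rather than extending the mask a window length beyond a dense tract.
Users with output from a dedicated recombination detector can substitute
it via `external_masks` / `--mask`.  Masking removes sites per strain;
pair distances exclude sites masked in either member, so masking never
increases a distance.  Clonal groups are single-linkage components at
post-masking d < 10; both thresholds are strict less-than.

Each clonal group is classified by the most specific metadata stratum
shared by all members (host sample → family → community → city → province
→ country; otherwise inter-country); a group confined to one host is
reported as single-colonization evidence, not transmission, and
cross-host-species flags are raised when members span species.
Directionality and timing of transmission are out of scope.

## Community statistics

Taxa below 0.005 % dataset-wide relative abundance (taxon total over grand
total; a per-sample variant is available) are removed, then abundances are
Hellinger-transformed (y′ = √(y/row total), unit row sum of squares).
tb-RDA is least-squares constrained ordination on dummy-coded covariates,
reporting full-model R² (and adjusted R²) plus per-covariate *marginal*
(unique-contribution) R² with permutation p-values
((count ≥ observed) + 1)/(permutations + 1), 1000 permutations by default.
PERMANOVA uses Gower-centered inner products of the Euclidean distance with
*sequential* (Type I) partitioning in the covariate order given — the
convention pair (sequential PERMANOVA, marginal RDA) is this package's
resolution of an otherwise underdetermined choice.  On a Euclidean distance
of the same response the two R² partitions agree (Gower identity, tested to
1e-9), and a 1-dimensional response reduces PERMANOVA to one-way ANOVA.
Group comparisons use tie-corrected Kruskal–Wallis plus pairwise
Mann–Whitney U (exact enumeration for tie-free groups of ≤ 8, otherwise the
tie/continuity-corrected normal approximation) over age bins
0–17 / 18–45 / 46–65 / >65, with a compact letter display built from
maximal cliques of the non-significance graph.

## Synthetic cohorts

The generator is star-like, not coalescent: a random reference, one
ancestor branch per population (`pop_divergence_scale × mutation_scale`
expected substitutions/site; default 2 × 0.006, giving a 3:1
between:within pairwise divergence ratio), and independent tip branches
(`mutation_scale = 0.006`, ≈ 600 SNPs between two strains of one
population on the default 50 kb genome — chosen so that ordinary
population members sit above the 300-SNP pruning threshold while planted
clones sit below it).  Clonal expansions give each member
⌊max_pairwise/2⌋ private substitutions on a shared clone ancestor, so the
configured pairwise bound holds by construction.  Recombination imports
are tracts of elevated substitution density (background × multiplier, one
tract per strain per configured spec, default 5 kb at 20×), which is
exactly the signal the masking stage detects — no donor-sequence copying
is performed, so the generator cannot exercise donor attribution, only
detection and masking.  The age-associated SNP triplet is planted by
overwriting carrier/non-carrier states at three random sites (carrier
probability 0.4), and age = 20 + effect × carriage + N(0, 5) years with a
default effect of 40 years per allele.  Provinces map 1:1 to populations
with 5 % random leakage; clone-group members share a household so planted
transmission is classifiable from metadata.  Population-specific genes are
carried by 100 % of their population and 0 % of others; 80 % of them are
assigned one COG category and one KEGG pathway to plant enrichment signal.
Abundances are Dirichlet-multinomial with a log-linear age effect on the
focal taxon (default −0.02/year) and Gaussian province shifts.

What passing tests on these cohorts does *not* show: robustness to
unequal sampling, within-population phylogenetic structure beyond a star,
donor-traceable recombination, indels/rearrangements, sequencing or
assembly error, or compositional artifacts of real amplicon data.

## Numerical choices and problem sizes

Fisher tests use exact integer weights; OLS uses QR-based residualization;
MDS eigenvalues below 1e-9 of the leading magnitude count as zero;
silhouette ties prefer smaller K; permutation p-values always include the
identity permutation in numerator and denominator.  The test and
acceptance suites run on 50 kb genomes with 36–150 strains per cohort, 20
seeds for population recovery, 50 for transmission recovery and GWAS
power, and 200 replicates for null calibration — sizes chosen so the full
suite completes in well under a minute per stage while keeping Monte-Carlo
error far from the asserted margins.

## Known limitations

The painting and masking stages are transparent approximations of
HMM/MCMC-based tools and inherit none of their uncertainty estimates; the
one-vs-rest scans are anticonservative by design (no structure
correction); Firth p-values are Wald-based rather than penalized
likelihood-ratio; and Mash distances are computed on gap-stripped aligned
sequences, so unaligned accessory content does not contribute k-mers.
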