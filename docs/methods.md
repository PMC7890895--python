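# Methods

This note documents the models, rules, and numerical choices behind
`regevo`, and what the synthetic-data generator does and does not emulate.

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED convention) internally; 1-based
inclusive inputs can be declared per file (`dialect="one-based"`) and are
converted on read. Strand is parsed and written but ignored by every overlap
computation: regulatory region calls are strandless. Overlap rules come in
three flavors, and the distinction matters:

* **Subject-length 50%** — "X overlaps Y with ≥50% of its length" is the
  fraction of the *subject* X's length. Used for promoter (H3K4me3 vs
  H3K27ac) and enhancer (H3K27ac vs H3K4me1) calling. For the enhancer rule
  the subject defaults to the H3K27ac peak; `ae_overlap_subject="k4me1"`
  flips the side, since the definition's wording admits both readings.
* **Reciprocal 50%** — both fractions must reach 50%. Used only for
  reproducible-peak detection between replicates.
* **Either-side 50%** — at least one of the two fractions reaches 50%.
  Used for cross-tissue linking (same-signature sharing and cross-signature
  dynamics).

Cross-species maintenance, triad membership, enhancer/gene association, and
repeat partitioning use ≥1 bp overlap; only the repeat enrichment
`half_region` mode and the random-placement control use a 50% coverage
criterion.

## Regulome construction

Per-replicate peaks are first reduced to a reproducible consensus: a peak is
kept iff some peak of another replicate overlaps it reciprocally by ≥50%;
connected groups of kept peaks are merged to their union span. Signature
calling then proceeds in a fixed order with a growing exclusion set:

1. every H3K4me3 peak covered ≥50% by an H3K27ac peak becomes an **AP**
   (with the H3K4me3 footprint); the exclusion set grows by the H3K4me3 peak
   and *every* H3K27ac peak touching it by ≥1 bp (maximal exclusion avoids
   double-counting shared acetylation blocks);
2. every remaining H3K27ac peak not touching the exclusion set, covered
   ≥50% by H3K4me1, becomes an **AE**;
3. every H3K4me1 peak with zero overlap against the *raw* H3K27ac and
   H3K4me3 consensus sets becomes a **PE** (the raw sets, not the exclusion
   set, per the definition of "primed").

Everything else is retained as unclassified. Within a tissue the three
signature sets are pairwise base-disjoint; the test suite verifies both this
and full equivalence with a per-base brute-force reimplementation on random
toy genomes.

Cross-tissue activity links same-signature regions directly (pairwise), not
by transitive closure — chains of partially overlapping regions across three
or more tissues would otherwise inflate sharing (a `transitive=True` flag
exists for sensitivity analysis). Regions linked across tissues with a
*different* signature are flagged intra-species dynamic (promoter↔enhancer
takes precedence over active↔primed when both occur) and are excluded from
specificity and evolution tallies unless explicitly requested. Specificity
is tissue-specific (1 tissue), tissue-shared (2+), or four-tissue-shared
(all tissues, configurable count). Nearest-promoter and nearest-TSS
assignments use edge-to-edge distance with a 1 Mb ceiling; ties break to
the lower start coordinate, then lexicographic sequence name.

## Cross-species projection and rates

Alignment maps are pre-extracted gapless block tables; a region's projected
footprint is the union of its block-mapped pieces. Footprint pieces more
than `cluster_gap` (default 10 kb) apart count as multiple mapping locations
and exclude the region from all counts — the gap value is a package choice,
exposed as a parameter. Maintenance requires ≥1 bp overlap with any
regulatory region of the other species, of any signature and tissue (a
`same_tissue` mode restricts partners to the query's home tissue).
1-to-1 status additionally requires a unique partner whose reciprocal
projection uniquely returns the query.

Pair-level fractions (maintenance, replicate reproducibility, promoter
switching) are reported as the mean of the two directional fractions × 100;
raw directional counts are always retained alongside. Rate fits are
per-category OLS of fraction on divergence time, with replicate-based zero
points entering as ordinary points at divergence 0; category comparisons use
the F-test of the divergence × category interaction in the joint two-category
model. When two categories are exactly parallel the interaction F ratio is
0/0; the fit reports p = 1 in that degenerate case (no evidence of
interaction). The interaction test otherwise matches a standard two-way
ANOVA on the linear model.

## Triads and the transition model

A genomic region enters a triad analysis iff it is 1-to-1 maintained across
all three species pairs with mutually consistent partners and is
intra-species dynamic in none of the three species. Rows are unordered
ingroup signature pairs; columns are outgroup signatures. Parsimony-usable
configurations are exactly {X,X}/outgroup-X (a stay) and {X,Y}/outgroup-X
(one X→Y change on an ingroup branch); {X,X}/outgroup-Y admits two equally
parsimonious histories and is excluded from model estimation while remaining
in the table. Pooling across triads sums raw counts before row
normalization. Row chi-square tests (df=2) scale the background shares to
the row total; zero expected cells raise an error advising a row merge.

Because a tissue-shared element appears once per active tissue in each
species' regulome, its cross-species partner set contains one region per
active tissue and it therefore fails the 1-to-1 uniqueness requirement; in
practice the 1-to-1 analyses (signature decomposition, triads) are carried
by tissue-specific elements. This is a consequence of keeping per-tissue
region identities all the way through rather than collapsing them, and it
is shared by the simulator and the analysis, so recovery tests remain
unbiased.

## Repeat statistics

Relative enrichment works within a repeat class: the denominator counts
regions of the set overlapping *any* repeat of the class (each region once),
the numerator those overlapping the given subgroup. A region overlapping
several subgroups counts once per subgroup, so shares can sum slightly above
100%; `strict_subgroup=True` instead attributes each region to its
largest-overlap subgroup. The two-proportion z-test is pooled and
uncorrected by default (`correction=True` applies the Yates-style continuity
correction, matching R's `prop.test`); Bonferroni divides by the number of
emitted matrix cells *before* the ≥100-occurrence display filter. Repeat
partition precedence is dynamic > recently-evolved > inactive: a repeat
under an evolutionarily dynamic region makes the stronger claim; repeats
touching only stable maintained regions fall into the inactive category.
Converting LINE percent divergence to absolute ages requires an external
substitution-rate constant and is deliberately left to the caller.

The random-placement control draws, for each real region, one random region
of identical length uniformly outside the regulatorily active intervals
(placement weighted by the number of admissible start positions per gap) and
scores merged-repeat coverage ≥50% of region length. It is deterministic
under its seed.

## The synthetic generator

The generator emulates: ancestral regions with configurable signature
proportions (default AP 0.2, AE 0.4, PE 0.4 — enhancers outnumber promoters
as in mammalian tissue panels) and tissue-specific fractions (AP 0.4,
AE 0.76, PE 0.83 — promoters widely shared, enhancers mostly
tissue-specific); survival along each branch of a newick phylogeny with
probability 1 − slope·t/100 (slope default 0.3 %/MY; an exponential mode
exists); signature switching by a per-MY row-stochastic matrix raised to the
branch length; per-slot alignment blocks lost at a per-MY rate along each
branch; per-replicate Gaussian boundary jitter (sd 10 bp) and dropout
(p 0.1) over three replicates; non-reproducible noise peaks; and L1/L2
repeats with family-specific length and divergence distributions (L1
younger and longer than L2) and a placement odds ratio favouring
tissue-specific regions (L1 2.0, L2 0.5). The default four-species tree
spans divergences of 21–96 MY.

Layout guarantees make oracle tests exact: each region occupies its own
slot (2.4 kb) with ≥600 bp margins; noise peaks live on a per-replicate
raster in the margins so they can neither touch true regions nor form
reproducible consensus across replicates (a `hard_noise` flag relaxes
this); with jitter and dropout at 0, regulome reconstruction equals the
recorded truth exactly, region for region.

Branch transition matrices use `expm(t·logm(M))` when the per-MY matrix has
a valid rate-generator logarithm (always the case for the near-identity
defaults), falling back to an integer matrix power otherwise; the method
used is recorded in the truth output.

What the generator does *not* emulate: sequence content (no nucleotides,
motifs, or mappability structure); regulatory gains along branches (new
regions arising after the root — turnover is loss-driven, so recently
evolved counts reflect loss in the partner lineage plus alignability loss,
not lineage-specific birth); inversions or rearrangements (blocks stay
collinear, so multi-mapping arises only from user-supplied maps);
tissue-set evolution (a region's active-tissue set is fixed at the root,
so intra-species dynamic regions do not arise spontaneously);
signature-dependent loss rates (loss may depend on specificity but not
signature); and correlated noise between marks. Passing recovery tests on
this generator therefore demonstrates correctness of the bookkeeping and
estimators under the stated generative model, not robustness to the full
messiness of real ChIP-seq.

Replicate dropout produces a known artifact worth stating: when an active
enhancer loses its H3K27ac consensus (two of three replicates dropping, a
~0.7% event per region at defaults), it is called PE, which downstream looks
like AE→PE switching. Transition-model recovery tests therefore run with
jitter and dropout at 0 to isolate estimator error; with default dropout the
apparent switching floor is of that order.

## Problem sizes and numerics

Test-suite simulations use 200–2,000 regions; transition-model recovery
runs use 20,000–40,000 ancestral regions (≈5,000–10,000 triad-usable
regions), sizes at which binomial noise on estimated transition rows is
well inside the asserted tolerances. The df=2 chi-square p-value has the
closed form exp(−χ²/2), used as an oracle at 1e−9; the uncorrected
two-proportion z equals the square root of the 2×2 chi-square statistic,
checked at 1e−6 in p; rank-sum tests use the exact null for tie-free
samples up to 25 values. OLS slopes are checked against a raw
normal-equations solution at 1e−9.

## Known limitations

* Maintenance decay is linear per branch and multiplicative along paths, so
  realized pair-level decay is slightly shallower than the nominal slope at
  large divergences, and calling noise lowers the divergence-0 intercept
  below 100%; fitted slopes on simulator output are correspondingly a little
  shallower than the configured per-branch value.
* The 1-to-1 restriction excludes tissue-shared elements (see above);
  analyses limited to 1-to-1 regions are analyses of the tissue-specific
  regulome under this data model.
* The background ("All") row of a triad table is computed per triad;
  pooled-model estimation sums counts across triads, but cross-triad
  heterogeneity is not modeled.
* Repeat age is reported on the percent-divergence scale only.
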