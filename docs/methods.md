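# Methods

This note records the statistical definitions, conventions and design
choices implemented in `sfbkit`, and what the synthetic-data generators
do and do not emulate.

## Alignments and gap handling

All statistics operate on pre-aligned, curated coding sequences; the
package performs no alignment or ORF detection (frame offset defaults
to 0 and is configurable). Gap handling is **complete deletion**: every
column containing a gap in any sequence is removed before analysis, and
the removal returns a column index map for traceability. The one
deliberate exception is the Poisson protein distance, which uses
**pairwise deletion** of ambiguous positions (gaps/X) by default — the
convention of the standard tree-building tools for amino-acid distances
— with complete deletion available by flag. Columns containing `N`
exclude the affected sequences from that column's counts, and per-site
normalisation uses the pairwise-valid length, mirroring complete
deletion at the pair level.

Internal stop codons are rejected at load time unless explicitly
allowed (`allow_stops`), in which case stop-containing codons are
treated as missing by the codon statistics; a terminal stop codon is
dropped at translation.

## Site spectrum and mutation counts

A column is *segregating* if it carries ≥ 2 nucleotide states,
*parsimony-informative* if ≥ 2 states each occur ≥ 2 times, and a
*singleton site* otherwise, so S = singletons + parsimony-informative.
The total mutation count η sums (distinct states − 1) per column, so a
triallelic column contributes two mutations but one segregating site.
This distinct-states−1 definition of "total mutations" matches the
per-class counts the report tables print.

## Nei–Gojobori counting

Sites: each codon position contributes (number of synonymous
single-nucleotide changes)/3 synonymous sites; changes that would create
a stop codon are removed from both numerator and denominator
contributions, so a stop-adjacent codon totals slightly fewer than
3 sites (e.g. TGG: 0 synonymous + 7/3 non-synonymous). Site counts are
averaged over all sequences in the sample (or over each pair for
pairwise proportions).

Differences: for two codons differing at 1–3 positions, all orderings of
the changes (1, 2 or 6 pathways) are walked and the per-pathway
synonymous/non-synonymous step counts averaged; pathways whose
intermediate codons are stops are excluded. If every pathway is blocked
(possible only for some 3-step pairs), the full pathway set is used and
a warning logged rather than failing — these pairs are rare and the
difference total is unaffected.

π_S and π_A divide each pair's summed synonymous/non-synonymous
differences by the pair-averaged site counts; the Jukes–Cantor
correction is applied **per pair**, then averaged (the composition used
by the standard implementations), never to the averaged proportion. The
correction is undefined at p ≥ 3/4 and raises rather than silently
truncating. Divergence K_S/K_A averages the same pairwise quantities
over all (focal, comparator) pairs; the comparator is an explicit
argument (ancestral or outgroup alleles aligned to the same columns)
because a divergence without a designated comparator is ambiguous — an
intra-sample mode is available by omitting it.

## Neutrality tests

Tajima's D uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
with S = segregating sites and k̂ = mean pairwise differences. Two exact
degeneracies are handled explicitly: at n = 2 all variance coefficients
vanish, and at n = 3 both c₁ and c₂ are identically zero, so D is
undefined (reported as null, never 0 or ±∞) whenever the variance is
non-positive — hence the recommendation of n ≥ 4.

The partitioned statistics D_S and D_A plug class-specific inputs into
the same formula: S_class is the pathway-classified count of segregating
synonymous (resp. non-synonymous) mutations, rounded by largest
remainder to integers, and k̂_class is the mean over pairs of the summed
pathway-averaged per-codon synonymous (resp. non-synonymous)
differences. This is the construction implied by reporting one D per
site class from a single dataset; no closed-form reference exists for it.

Fu & Li's D\* and F\* use the no-outgroup ("starred") variants with η =
total mutations and η_s = mutations carried by exactly one sequence, and
the corrected variance coefficients of Simonsen, Churchill & Aquadro
(1995) adopted by the common implementations. The outgroup variants
D and F are deliberately out of scope.

The McDonald–Kreitman table counts **mutations** (not sites): a codon
column variable within the focal sample contributes polymorphic
mutations regardless of the outgroup state (the standard convention when
a site is both polymorphic and divergent); a focal-monomorphic column
differing from the outgroup consensus codon contributes fixed
differences. Fractional pathway-typed counts are rounded by largest
remainder within each table row, because the report format is integer
counts. Significance is a two-sided Fisher exact test by default (exact
enumeration of the conditional null is the appropriate small-sample
choice; a G-test is available by flag). Undefined ratios (zero
denominators) are reported as nulls.

## Trees

Poisson-corrected distance d = −ln(1 − p) on the proportion p of
differing amino acids per pair (pairwise deletion, above); p = 1 is an
error rather than an infinite distance. UPGMA agglomerates by
group-size-weighted average distances; ties are broken on the
lexicographically smallest member labels, making topologies reproducible
— with all-equal distances the output is the label-ordered caterpillar.
The result is ultrametric to 1e-9 by construction and reconstructs
ultrametric input matrices exactly. Bootstrap supports resample columns
with replacement (one index-vector draw per replicate from a seeded
generator, consumed in replicate order); support is the percentage of
replicate trees containing each clade of the point-estimate tree.
Degenerate resamples (a pair with no comparable or all-differing sites)
are skipped and count against support.

## Haplotype networks and dating

The minimum spanning network keeps edge (u,v,w) iff u and v are not
connected using only edges of weight < w − ε; at ε = 0 this is exactly
membership in ≥ 1 minimum spanning tree (verified against brute-force
enumeration of all spanning trees). Identical sequences collapse into
one node carrying multiplicity. Character weights are uniform (1 per
site).

The median-joining construction iterates: rebuild the ε-MSN over current
nodes, scan triples joined by two incident edges, and add the per-site
majority median vector with the largest reduction in local connection
cost (ties broken lexicographically on the vector), until a fixed point;
median vectors that no longer reduce the spanning cost are pruned.
Because medians are only ever added when they reduce cost, the final
network's minimal spanning length never exceeds the MST length over the
observed haplotypes alone. Note that a median can *replace*
observed–observed MST edges by cheaper two-edge paths, so the final
graph is not guaranteed to contain an MST over observed nodes as a
subgraph — the guarantees tested are: all observed haplotypes present,
connectivity, and spanning cost ≤ observed-MST cost.

The rho statistic of an ancestral node against a descendant set is the
mean shortest-path mutation count in the network (the network
generalisation of tree path length; equal-cost path ties are irrelevant
since only the count enters). Ages are **rho/μ** with μ in mutations per
year (default 10⁻³, the rate used for gametophytic self-incompatibility
alleles): a rho of 25.5 gives 25,500 years. Some sources describe this
conversion as "multiplication with the mutation rate"; published ages
are consistent with division by a per-year rate, which is what the
arithmetic identity age = ρ/μ implements.

## SSR diversity and linkage disequilibrium

He uses Nei's unbiased estimator (2n/(2n−1))(1 − Σp²) by default — the
default of the standard population-genetics packages — with the plain
1 − Σp² by flag; PD = 1 − Σ(genotype frequency)² over observed unordered
genotypes. Both are invariant to allele relabelling and individual
order.

Rare alleles with sample frequency strictly below the threshold (default
5%) are removed before LD analysis by setting the carrying calls to
missing; the filter is a **single pass** (frequencies are not recomputed
on the filtered data, so a retained allele's post-filter frequency may
drop below the threshold — documented behaviour, not a bug). Loci left
monomorphic are excluded from LD with a logged warning.

LD on unphased diploid data uses the composite (Burrows/Weir)
disequilibrium: with per-individual allele dosages x, y ∈ {0,1,2},
r_ab is the Pearson correlation of dosages — i.e. the composite Δ
normalised by Hardy–Weinberg-departure-corrected variances, which is the
form appropriate when genotype, not gamete, frequencies are observed
(a plain p(1−p) denominator would give r² = 4 on perfectly coupled
homozygote data). Biallelic phased-equivalent data reduce it to the
squared Pearson correlation of allele indicators. Significance defaults
to a seeded permutation test (individuals' genotypes at one locus
permuted jointly across its alleles; tie-inclusive counting, P =
(1 + #{r²_perm ≥ r²_obs})/(1 + n_perm)); the asymptotic χ² (n·r², 1 df)
is available by flag but not the default at panel sizes around n = 24.
Because dosages are integers the permutation distribution of r² has
heavy ties, so null P values are conservative near 1 while remaining
calibrated in the decision-relevant lower tail (empirical size ≈ 4–5% at
α = 0.05). Locus-level r² is the p_a·p_b-weighted mean over evaluable
allele pairs; the locus-pair P is the Bonferroni-adjusted minimum
allele-pair P; "% significant blocks" counts allele-pair tests at α.
Missing genotypes are dropped pairwise per locus pair.

## Synthetic data

`simulate_neutral_sample` draws a standard neutral coalescent genealogy
(exponential times at rate k(k−1)/2 in units of 2N) and places
Poisson(θ·branch/2) mutations under infinite sites onto a random
monomorphic background, one distinct site and one derived state per
mutation (no back-mutation) — the assumptions under which E[S] = θa₁ and
E[π] = θ, both verified by the tests. Mutation counts exceeding the
sequence length are redrawn a bounded number of times, then error.

`simulate_codon_sample` evolves a random stop-free codon sequence down
the same genealogy: single-nucleotide changes are proposed uniformly,
stops rejected, synonymous changes always accepted and non-synonymous
ones with probability min(1, ω). This acceptance filter makes the
realised dN/dS ≈ ω by construction — adequate for estimator-recovery
tests, but it is not a full codon substitution model (no
transition/transversion bias, no rate variation, no codon-frequency
model). The outgroup diverges from the root with Poisson(t_div·3L)
proposals, t_div in expected proposals per site.

`simulate_ssr_genotypes` samples two alleles per individual per locus
under Hardy–Weinberg equilibrium. Defaults emulate a small germplasm
panel: 24 diploid individuals, 10 loci whose configured allele counts
are (6,3,5,4,3,5,4,2,4,3) with geometrically decaying frequencies
(ratio 0.3, giving mean He ≈ 0.44); in samples this small the observed
allele count can fall below the configured one. A designated locus pair
can be made biallelic with prescribed normalised association D′
(infeasible D′ raises with the feasible bound). The generators do not
model recombination, selection, demography or stepwise microsatellite
mutation, so passing tests demonstrate estimator correctness under the
stated null/selective models, not robustness to those real-data
complications.

Every generator derives all randomness from the single configured seed
(sub-streams by fixed offsets), so outputs are bit-reproducible and
independent of call order.

## Problem sizes used by the acceptance script

Null calibrations use 500 neutral replicates (n = 13, θ = 5, L = 1000);
ω = 1 recovery uses 40 replicates (n = 13, θ = 40, 400 codons) and the
ratio of summed diversities; ω = 0.2 divergence recovery uses 30
replicates (n = 4, 500 codons, t_div = 0.08); the LD type-I rate uses
300 independent-locus panels (n = 100, 200 permutations). These sizes
put the Monte-Carlo standard errors well inside the tolerance bands
while keeping the full run under a minute on one CPU.

## Known limitations

- The MK mutation-typing of codons differing at > 1 position relies on
  pathway averaging plus largest-remainder rounding; with extreme
  divergence the integer rounding can shift single counts between cells.
- Partitioned Tajima's D has no published closed form; the construction
  here is internally consistent (classes sum to the totals) but other
  software may partition differently at multi-hit codons.
- The median-joining implementation adds one best median per round and
  prunes by spanning-cost comparison; for large, highly reticulate
  datasets the classic implementation's simultaneous median batches may
  produce additional (cost-neutral) medians.
- Permutation LD P values are conservative under heavy ties (integer
  dosages); use more permutations or the χ² flag for fine-grained
  upper-tail comparisons.
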