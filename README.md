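# sfbkit

Molecular-evolution and population-genetics toolkit for analysing
S-locus genes — in particular the pollen-side *SFB* (S-haplotype-specific
F-box) alleles of self-(in)compatible *Prunus* — and the microsatellite
neighbourhood of the S-locus.

In *Prunus*, gametophytic self-incompatibility is controlled by a pistil
S-RNase and a pollen SFB gene at the S-locus. Asking *how* a species lost
self-incompatibility (as peach did) turns into a set of standard
molecular-evolution questions about its SFB alleles: are non-synonymous
changes accumulating like neutral ones? Is variation skewed toward rare
variants? Do the alleles still show the footprint of balancing selection
(significant linkage disequilibrium around the S-locus)? How old are the
allele lineages? `sfbkit` implements the full battery of statistics those
questions require, on plain FASTA alignments and genotype tables, with a
seeded synthetic-data generator so that every stage is testable without
any external downloads.

## What it computes

**Coding-sequence diversity** (`sfbkit.diversity`)
- site spectrum: segregating sites *S*, singletons, parsimony-informative
  sites, total mutations η (= Σ per site of distinct states − 1)
- nucleotide diversity π (mean pairwise difference per site), with the
  Jukes–Cantor multiple-hit correction d = −¾ ln(1 − 4p/3)
- Nei–Gojobori (1986) approximate counting: expected synonymous /
  non-synonymous sites per codon and pathway-averaged synonymous /
  non-synonymous differences per codon pair (stop-codon pathways excluded)
- π_S, π_A within a sample and K_S, K_A against a designated
  comparator/ancestral set, with the K_A/K_S and π_A/π_S ratios

**Neutrality tests** (`sfbkit.neutrality`)
- Tajima's D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)), total and partitioned into
  synonymous (D_S) and non-synonymous (D_A) site classes
- Fu & Li's D\* and F\* (no-outgroup variants, singleton-based)
- McDonald–Kreitman 2×2 test (fixed vs polymorphic × synonymous vs
  non-synonymous) with f_A/f_S, P_A/P_S, the neutrality index and a
  two-sided Fisher exact P

**Trees and networks** (`sfbkit.trees`, `sfbkit.networks`)
- Poisson-corrected protein distances d = −ln(1 − p), UPGMA with
  deterministic tie-breaking, column-bootstrap supports, Newick output
- minimum spanning networks (union of all MSTs over Hamming distances,
  ε-relaxed) and median-joining networks with inferred median vectors
- rho dating: mean mutational distance from an ancestral node, converted
  to years as age = ρ/μ (μ in mutations per year; μ = 10⁻³ for S-alleles)

**SSR diversity and LD** (`sfbkit.ssr`)
- per-locus Ao, Ho, He (Nei's unbiased), PD = 1 − Σ(genotype freq)²
- rare-allele exclusion (frequency < 5% by default, strict)
- composite (Burrows/Weir) allele-level r² for unphased diploid
  genotypes with seeded permutation P values, locus-level summaries and
  a heatmap-ready P matrix

**Synthetic data** (`sfbkit.simulate`) — neutral coalescent samples
under infinite sites, codon alignments with an acceptance-controlled
dN/dS ratio ω plus a diverged outgroup, and HWE genotype panels with
tunable two-locus association, all bit-reproducible from a seed.

## Worked example

Simulate 13 coding sequences (350 codons) under purifying selection
(ω = 0.3) with a diverged outgroup, then run the diversity and
neutrality stages:

```
sfbkit simulate --model codon --seed 42 --n 13 --theta 30 \
    --length 350 --omega 0.3 --t-div 0.06 --out sim
sfbkit diversity  --in sim/codon_focal.fasta \
    --comparator sim/codon_outgroup.fasta --out results
sfbkit neutrality --in sim/codon_focal.fasta \
    --outgroup sim/codon_outgroup.fasta --out results
```

`results/diversity.tsv`:

```
Name         N   Poly.S  Sing  Par.Inf  pi     M   Syn.M  N.Syn.M  piS    piA    piA/piS  KS     KA     KA/KS
codon_focal  13  49      11    38       0.018  49  25     24       0.040  0.012  0.30     0.075  0.022  0.29
```

`results/neutrality.tsv`:

```
Name         fS  fA  PS  PA  fA/fS  PA/PS  D_T   D_S   D_A   D*    F*    MK_P
codon_focal  8   9   25  24  1.12   0.96   0.71  0.73  0.64  0.59  0.71  1.0000
```

Reading the rows: of the 49 mutations segregating in the sample, about
half are synonymous even though three quarters of the sites are
non-synonymous, so per-site diversity at non-synonymous sites is much
lower (π_A/π_S = 0.30) — and divergence to the outgroup shows the same
deficit (K_A/K_S = 0.29), both recovering the simulated ω = 0.3. The MK
table is close to homogeneous (f_A/f_S ≈ P_A/P_S, Fisher P = 1.0): the
same selective regime governs polymorphism and divergence here, unlike
the purifying-selection signature (f_A/f_S ≪ P_A/P_S) seen when
deleterious variants segregate but never fix.

Other stages work the same way: `sfbkit tree` (UPGMA Newick with
bootstrap), `sfbkit network` / `sfbkit rho` (median-joining networks and
ρ/μ ages), `sfbkit ssr` / `sfbkit ld` (genotype diversity tables and the
LD P matrix), and `sfbkit report` to run every applicable stage at once.
A TOML config file can set any option (`sfbkit --config run.toml report …`;
command-line flags win).

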