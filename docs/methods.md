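# Methods

This note documents the models implemented in `serpan`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a user should know before trusting a result.

## The analysis model

The object of study is a focal clade of conspecific bacterial strains
sampled from two habitat classes (serpentine = high-nickel soil,
non-serpentine) across several reserves. The working hypothesis is
ecotypic differentiation at few loci inside a cohesive population: most of
the genome is shared and recombining across habitats, while habitat-specific
selection maintains a small set of adaptive accessory genes, typically
acquired horizontally and physically clustered.

### Ortholog groups and the presence/absence matrix

Gene calls arrive as BLAST-style hit tables. Hits are retained when
`alignment_length / query_length > 0.80`, `E-value < 1e-20` and
`percent identity > 50` — all three strict inequalities. The overlap
denominator is the query length by default; whether overlap should instead
be measured on the subject is genuinely ambiguous, so it is a parameter
(`overlap_denominator`). Genes whose best filtered hit is the same
reference proteome entry share that entry's ortholog group. Remaining
("de novo") genes are grouped by single-linkage closure over reciprocal
best hits: `b` is `a`'s unique best hit (max bitscore, ties broken by min
E-value then lexicographic subject id, ties flagged in the log) and vice
versa. Pairwise reciprocity alone does not define multi-strain groups, so
single-linkage closure is the deliberate extension; a gene claimed by both
a reference group and a closure stays with the reference group, and one
gene per strain per group is enforced (best bitscore wins).

Core genes are present in every strain of the chosen subset; accessory
genes are present in at least one and absent from at least one; genes absent
from the whole subset belong to neither compartment. A subset whose
pan-genome is empty raises an error — this is the degenerate case the
dropout simulation at rate 1.0 must hit.

SNPs are called per core-gene alignment column; any column containing a
gap or ambiguity character in any subset row is skipped entirely. The
alternative (pairwise deletion) was rejected because it breaks the
rectangular genotype matrix the distance and association code assume.
Multi-allelic columns are emitted but flagged, and excluded from
association.

### Structure-corrected association

Growth (OD600) is regressed by OLS on an intercept plus the first K−1
admixture loading columns (the last is dropped; Q rows sum to one). The
residuals — which sum to zero — are the tested phenotype. Each accessory
gene defines carrier/non-carrier classes; each biallelic SNP defines allele
classes. Classes with minor size < 2 ("singletons", on either side) and
fixed variants are skipped with reason codes. The test is the two-sided
Wilcoxon rank-sum: exact null distribution when the smaller class has ≤ 25
observations and no ties occur (residuals are continuous, so ties are
essentially impossible), otherwise the normal approximation with tie and
continuity corrections. A fully tied input returns p = 1.

Multiplicity: Bonferroni (`min(1, m·p)`) for the strict tier and
Benjamini–Hochberg step-up for the FDR tier (default 10 %). A Storey
q-value with π₀ estimated at λ = 0.5 is available but not the default — BH
is simpler, monotone, and adequate at these scales. Effects are reported on
the *raw* phenotype (mean of carriers − mean of non-carriers) together with
carrier frequencies among serpentine and non-serpentine strains; tests use
residuals, effects deliberately do not, so the effect column stays in
interpretable OD600 units.

The low-nickel phenotype is run through the identical scan as a negative
control; the pipeline reports its candidate count at a laxer (20 %) FDR
level, expected to be zero.

### Candidate clusters

On each contig (genes sorted by start, non-overlapping, 1-based inclusive
coordinates), a seed is a run of ≥ 4 consecutive candidate genes —
"tandem" is read as consecutive in gene order, regardless of strand or
intergenic distance. Seeds grow by absorbing any candidate whose proximal
coordinate lies within 10 kb of the current cluster edge (inclusive
boundary); intervening non-candidates are spanned but not members; growth
iterates to a fixpoint and touching clusters merge. Measuring the gap from
the cluster edge to the gene's *near* side (start when extending right, end
when extending left) is the only reading under which cluster calls are
exactly invariant to mirroring contig coordinates, which the tests enforce.
Clusters are matched across strains by single-linkage on candidate-set
Jaccard similarity ≥ 0.5, and order conservation within a family is the
mean pairwise LCS of member order divided by the shorter member list.

### Donor-distance (HGT) test

Each accessory gene carries the 16S divergence between the focal clade and
the lineage of its closest homolog. Candidates acquired from outside the
clade's usual gene pool should show an upward shift. Both a two-sample KS
test (exact when n·m ≤ 10 000) and a Wilcoxon rank-sum are reported —
the two standard choices for this comparison — plus the raw mean
difference, for the full candidate set and nested FDR tiers (1 %, 5 %,
10 %). Acquiring the distances (homolog search, taxonomy, 16S alignment)
is out of scope; the module consumes a prepared table.

### Ka/Ks

The Nei–Gojobori (1986) estimator: fractional synonymous site counts per
codon (mutations producing stop codons are excluded from the possible
changes at a position), averaged over the two sequences; observed
differences averaged over all shortest mutational pathways, excluding
pathways through stop codons (falling back to all pathways if every one is
blocked); Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), undefined when
p ≥ 3/4. Genetic code: bacterial table 11. Implementations differ in stop
handling; ours agrees with Biopython's NG86 to within ~5–10 % relative and
exactly with a pathway-enumeration oracle under our stated convention.
Genes with Ka = 0 or Ks = 0 are excluded from the log10(Ka/Ks)
core-vs-accessory rank-sum comparison by default (a pseudocount option
keeps them). Which sequences are compared per gene is a caller decision;
the estimator takes one aligned pair.

### PERMANOVA

Core divergence is the proportion of differing SNP sites over sites called
in both strains; accessory divergence is Jaccard distance on gene sets
(simple mismatch available). The adonis-style partition Gower-centers
−½D², enters factors sequentially (Type-I, soil before reserve by default,
order exposed), computes SS via projection hat matrices, and pseudo-F
against the residual. p-values come from free permutation of strain labels
(no strata), with full enumeration when n! ≤ 10 000, otherwise the observed
labeling is counted in numerator and denominator. Bootstrap CIs resample
strains with replacement (duplicates have zero mutual distance by
construction of the resampled matrix); replicates that collapse a factor to
one level are discarded and counted.

## The synthetic generator

`SimConfig` defaults are the study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| strains | 19 + 19 across 3 reserves | focal clade size, both soils in all reserves |
| accessory spectrum | Beta(0.3, 0.3) | reproduces the rare-or-ubiquitous U shape; no parametric form is prescribed by the data |
| core_size / accessory_pool | 500 / 2000 | desk-scale rendition of a several-thousand-gene pan-genome; keeps a full run in seconds |
| subgroups | 2, Dirichlet(0.3) loadings, Fst 0.15 | two admixture subgroups with mostly-assigned strains |
| planted clusters | 13 genes / 30 kbp, perfect assortment, causal; 10 genes / 30 kbp and 11 / 15 kbp at 6/19 serpentine carriers | the three serpentine-only cluster geometries the analysis targets |
| phenotype | baseline 0.20 (high-Ni) / 0.60 (low-Ni), +0.28 OD600 per causal cluster, sd 0.05, structure effect 0.10 | additive Gaussian model on OD600; 0.28 is the targeted per-variant effect size |
| snp_sites | 2000 | scaled-down core-SNP panel |
| homolog_shift | 0.033 | planted donor 16S distance shift |

Accessory carriage: ancestral frequency from the Beta spectrum, diverged
per subgroup by a Balding–Nichols draw, strain carriage Bernoulli at the
admixture-weighted frequency — so gene content is structure-confounded, as
real accessory genomes are. SNPs follow the same scheme. Planted cluster
carriers are drawn as fixed counts (`round(assortment · n_serpentine)`),
not Bernoulli, so perfect assortment is exact by construction. High-Ni
growth = baseline + Σ causal effects carried + structure effect × first
subgroup loading + Gaussian noise; low-Ni growth omits the causal term
only. Layouts share one canonical gene order across strains (optionally
shuffled per strain outside cluster blocks); each planted cluster is a
contiguous block spread evenly across its configured span on a single
contig per carrier. All randomness flows from one integer master seed via
fixed-offset child streams (admixture, membership, SNPs, phenotypes,
layout, homolog, hits).

What the generator does *not* emulate: read-level sequencing and assembly
error (the dropout simulation is a gene-level stand-in for
draft-incompleteness, a design choice, not a reconstruction of any
particular read-level procedure), in-paralogs and gene fission/fusion,
strand structure and operons, recombination tracts along the chromosome
(sites are exchangeable), and 16S sequence evolution (donor distances are
drawn, not evolved). Passing tests therefore demonstrate statistical
correctness of the methods under a faithful confounding structure — not
robustness to assembly artifacts or annotation error in real draft
genomes.

The gene-dropout experiment hides each present call independently with
probability d and re-partitions; a core gene over S strains is misread as
accessory with probability 1 − (1−d)^S − d^S (the last term: a gene dropped
everywhere leaves the pan-genome entirely), which the closed-form checks
use with d^S negligible at tested parameters.

## Numerical choices and degenerate inputs

- Exact Wilcoxon threshold: smaller group ≤ 25 and no ties; configurable.
- Completely tied rank-sum inputs return p = 1 rather than a 0/0 variance.
- BH is computed by statsmodels; Bonferroni caps at 1; Storey π₀ is floored
  at 1/m.
- `partition_core_accessory` on an empty-pan subset, association on an
  empty class, KS/Wilcoxon on empty samples, homolog tables with no
  non-candidate reference, single-level PERMANOVA factors and unsorted or
  overlapping contig maps all raise `ValueError` with specific messages.
- Permutation p-values include the observed labeling (never 0); exact
  enumeration replaces sampling when n! ≤ 10 000.
- Bootstrap replicates that lose a factor level are discarded and counted;
  a run that cannot find non-degenerate replicates aborts.
- Cluster extension uses an inclusive 10 kb edge-to-near-side rule (see
  above) so mirror invariance is exact.

## Problem sizes

The shipped experiments use scaled-down sizes chosen to keep a complete
validation run in minutes on a single CPU: pipeline runs at the default
2000-gene accessory pool and 2000 SNPs; the power experiment uses a
300-gene pool and 100 (tests) or 20 (acceptance script) replicates; the
type-I experiment a 4500-gene pool so ≥ 2000 genes survive filtering; the
dropout experiment 200 core genes × 200 replicates. Statistical
conclusions (power ≥ 95 % for the planted cluster, type-I control,
unbiasedness of effect and shift estimates) are stated at these sizes.

## Known limitations

- NG86 is a counting estimator; it underestimates rates at high divergence
  compared with ML (Goldman–Yang) methods, which are out of scope.
- The Storey q-value uses a single-λ π₀ estimate, not the smoother.
- PERMANOVA uses free permutations; restricted/strata designs are not
  implemented.
- The orthology round-trip is validated on synthetic hit tables with clean
  homology signals; real BLAST output with paralogy and domain shuffling
  will exercise the tie-break and conflict rules far harder.
- File-mode ingestion trusts its inputs (matrices already partitioned by
  the caller's upstream tools); only shape and label consistency are
  checked.
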