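# serpan

Pan-genome association mapping of bacterial habitat adaptation, built around
the case of wild *Mesorhizobium* populations adapting to nickel-enriched
serpentine soil.

Soil bacteria that straddle contrasting habitats often stay genomically
cohesive — migration and recombination mix most of the genome across
habitats — while selection maintains differentiation at a handful of loci.
Finding those loci requires mapping phenotype (here, growth in high-nickel
medium, measured as OD600) onto two kinds of variation at once: the
presence/absence of accessory genes and SNPs in the core genome. `serpan`
implements that analysis end to end for a focal clade of strains sampled
from paired serpentine / non-serpentine soils across several reserves, and
ships a synthetic-population generator with planted ground truth so every
statistical step can be validated.

## What it computes

Given a strains × ortholog-groups presence/absence matrix **G**, a biallelic
SNP matrix **X**, growth phenotypes **y**, and an admixture Q-matrix:

1. **Pan-genome structure** — ortholog groups from BLAST-style hit tables
   (reference-gene assignment with overlap > 0.80, E < 1e-20, identity >
   50 %, plus single-linkage closure over reciprocal best hits),
   core/accessory partition per strain subset, gene frequency spectrum, and
   SNP calling from core-gene alignments.
2. **Structure-corrected association** — residuals
   r = y − ŷ(Q) from OLS on admixture loadings, then a two-sided Wilcoxon
   rank-sum test of r between carriers and non-carriers of every accessory
   gene (and every biallelic SNP's allele classes), excluding fixed variants
   and singletons; exact p-values for small groups, Bonferroni and
   Benjamini–Hochberg FDR control, and Table-style effects
   (mean OD600 of carriers − non-carriers on the raw phenotype) with
   per-soil carrier frequencies.
3. **Candidate clusters** — regions on single contigs seeded by ≥ 4 tandem
   candidate genes, extended while another candidate lies within 10 kb of
   the cluster edge, matched across strains by membership Jaccard, with
   habitat-assortment flags.
4. **Horizontal-transfer signal** — KS and Wilcoxon comparison of
   nearest-homolog 16S distances, candidates vs non-candidate accessory
   genes, per FDR tier.
5. **Molecular evolution** — Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor
   correction, and the core-vs-accessory comparison on log10(Ka/Ks).
6. **Biogeography** — adonis-style PERMANOVA (sequential sums of squares on
   the Gower-centered distance matrix) partitioning core SNP divergence and
   accessory Jaccard divergence by soil type and reserve, with permutation
   p-values and strain-level bootstrap confidence intervals for R².

The synthetic generator (`serpan.synthio`) emulates the study conditions:
38 focal strains (19 serpentine + 19 non-serpentine, three reserves), a
U-shaped Beta(0.3, 0.3) accessory frequency spectrum, two admixture
subgroups that leak into allele frequencies and phenotypes, planted
habitat-assorting clusters (a 13-gene perfectly assorting causal cluster in
a 30 kbp span plus two partial clusters), a +0.28 OD600 growth effect per
causal cluster in nickel, a +0.033 donor 16S distance shift for candidate
genes, and a gene-dropout simulation quantifying how draft-genome misses
distort the core/accessory partition.

## Worked example

```python
from serpan import pipeline

cfg = pipeline.RunConfig(out_dir="demo_run", seed=42, n_perm=199, n_boot=50)
report = pipeline.run_all(cfg)
print(report.summary)
```

prints (reformatted):

```
n_core: 922            n_accessory: 1166
n_gene_candidates_fdr: 36   (Bonferroni: 34)
n_snp_candidates_fdr: 0     (Bonferroni: 0)
n_lowNi_gene_candidates: 0
n_clusters: 31  in 3 families;  families with >= 10 candidates: 3
n_perfectly_assorting_genes: 13   largest_family_span_bp: 30000
hgt_mean_shift: 0.0374
permanova: accessory_soil_R2 0.057, core_soil_R2 0.027,
           accessory_reserve_R2 0.048, core_reserve_R2 0.048
```

Reading this: the scan over 1166 accessory genes recovers the planted
causal clusters (36 candidates at 10 % FDR, 34 surviving Bonferroni) and no
false hits on the low-nickel control phenotype; the cluster caller finds the
13 perfectly soil-assorting genes inside one 30 kbp family; candidate genes'
closest homologs are ~0.037 more divergent at 16S than those of other
accessory genes (planted shift 0.033); and soil type explains more
accessory-genome than core-genome variance while reserve explains little of
either — the signature of gene-specific, habitat-linked adaptation inside an
otherwise well-mixed population. Every file behind these numbers
(association tables, cluster families, PERMANOVA tables, NEXUS distance
exports, a markdown report and a JSON manifest) is written under
`demo_run/`.

A CLI mirrors the library: `serpan simulate`, `serpan assoc`,
`serpan clusters`, `serpan hgt-test`, `serpan biogeo`, `serpan run`.

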