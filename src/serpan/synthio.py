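"""Synthetic pan-genome populations for serpentine-adaptation association studies.

This module generates strain collections with the statistical structure the
downstream analyses assume: a U-shaped accessory-gene frequency spectrum,
admixture between subpopulations that leaks into both allele frequencies and
growth phenotypes, planted habitat-assorting gene clusters with additive
effects on growth in nickel, draft-genome-like contig layouts, and a
nearest-homolog 16S distance table with an upward shift for candidate genes.
It also provides the gene-dropout simulation used to quantify how draft-genome
incompleteness distorts the core/accessory partition.

All randomness flows from a single integer master seed; each component draws
from a child stream spawned at a fixed offset, so outputs are reproducible
gene-for-gene under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pangenome

__all__ = [
    "ClusterSpec",
    "SimConfig",
    "SyntheticTruth",
    "PopulationDataset",
    "simulate_population",
    "simulate_phenotypes",
    "fragment_genomes",
    "simulate_homolog_distances",
    "simulate_hit_tables",
    "simulate_accessory_identification",
    "core_alignments",
]

# fixed spawn keys for per-component child RNG streams
_STREAMS = {
    "admixture": 0,
    "membership": 1,
    "snp": 2,
    "phenotype": 3,
    "layout": 4,
    "homolog": 5,
    "hits": 6,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[component],))
    )


@dataclass(frozen=True)
class ClusterSpec:
    """A planted positional cluster of accessory genes.

    assortment is the fraction of serpentine strains carrying the cluster and
    leak the fraction of non-serpentine strains carrying it; assortment=1.0
    with leak=0.0 gives a perfectly habitat-assorting cluster.
    """

    n_genes: int
    span_bp: int
    assortment: float = 1.0
    leak: float = 0.0
    causal: bool = True

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("ClusterSpec.n_genes must be >= 1")
        if self.span_bp < self.n_genes * 100:
            raise ValueError("ClusterSpec.span_bp must be >= n_genes * 100")
        for name in ("assortment", "leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ClusterSpec.{name} must lie in [0, 1]")


def _default_clusters() -> list[ClusterSpec]:
    # one large perfectly assorting cluster plus two partial ones, the
    # geometry of the three serpentine-only clusters the analysis targets
    return [
        ClusterSpec(n_genes=13, span_bp=30_000, assortment=1.0, leak=0.0, causal=True),
        ClusterSpec(n_genes=10, span_bp=30_000, assortment=6 / 19, leak=0.0, causal=True),
        ClusterSpec(n_genes=11, span_bp=15_000, assortment=6 / 19, leak=0.0, causal=True),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    Default sizes are a desk-scale rendition of a 38-strain focal clade split
    evenly between serpentine and non-serpentine soil across three reserves,
    with a Beta(0.3, 0.3) accessory frequency spectrum (rare-or-ubiquitous),
    two admixture subgroups, and a 0.28 OD600 growth effect per causal
    cluster in nickel-enriched medium.
    """

    n_serpentine: int = 19
    n_nonserpentine: int = 19
    n_reserves: int = 3
    core_size: int = 500
    accessory_pool: int = 2000
    freq_spectrum_shape: tuple[float, float] = (0.3, 0.3)
    n_subgroups: int = 2
    admixture_alpha: float = 0.3
    subgroup_fst: float = 0.15
    planted_clusters: tuple[ClusterSpec, ...] = field(
        default_factory=lambda: tuple(_default_clusters())
    )
    phenotype_effect: float = 0.28
    phenotype_sd: float = 0.05
    structure_effect: float = 0.10
    baseline_high_ni: float = 0.20
    baseline_low_ni: float = 0.60
    snp_sites: int = 2000
    contig_mean_genes: int = 100
    gene_length_bp: int = 900
    intergenic_bp: int = 100
    shuffle_noncluster: bool = False
    homolog_shift: float = 0.033
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_serpentine": self.n_serpentine,
            "n_nonserpentine": self.n_nonserpentine,
            "n_reserves": self.n_reserves,
            "core_size": self.core_size,
            "accessory_pool": self.accessory_pool,
            "n_subgroups": self.n_subgroups,
            "snp_sites": self.snp_sites,
            "contig_mean_genes": self.contig_mean_genes,
            "gene_length_bp": self.gene_length_bp,
            "intergenic_bp": self.intergenic_bp,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"SimConfig.{name} must be >= 1")
        if self.phenotype_sd <= 0:
            raise ValueError("SimConfig.phenotype_sd must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("SimConfig.dropout_rate must lie in [0, 1]")
        if not 0.0 < self.subgroup_fst < 1.0:
            raise ValueError("SimConfig.subgroup_fst must lie in (0, 1)")
        a, b = self.freq_spectrum_shape
        if a <= 0 or b <= 0:
            raise ValueError("freq_spectrum_shape parameters must be positive")
        for spec in self.planted_clusters:
            spec.validate()
        n_planted = sum(c.n_genes for c in self.planted_clusters)
        if n_planted > self.accessory_pool:
            raise ValueError(
                f"planted cluster genes ({n_planted}) exceed accessory_pool "
                f"({self.accessory_pool})"
            )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator — the recovery target."""

    causal_gene_ids: set[str]
    strain_subgroup_loadings: pd.DataFrame  # strains x subgroups, rows sum to 1
    true_effects: dict[str, float]  # gene -> OD600 effect of its cluster
    planted_cluster_coords: dict[str, dict[str, tuple[str, int, int]]]
    cluster_genes: dict[str, list[str]]  # cluster id -> ordered member genes
    cluster_carriers: dict[str, list[str]]  # cluster id -> carrier strains


@dataclass
class PopulationDataset:
    """All emitted tables for one simulated population."""

    strains: pd.DataFrame  # strain, soil, reserve
    presence: pd.DataFrame  # strains x ortholog groups, 0/1
    group_origin: pd.Series  # gene -> "reference" | "de-novo"
    snp: pd.DataFrame  # strains x sites, 0/1 (allele index)
    snp_info: pd.DataFrame  # site, gene_id, column, ref, alt
    phenotypes: pd.DataFrame  # strain, growth_highNi, growth_lowNi, soil, reserve
    q_matrix: pd.DataFrame  # strains x subgroups
    layouts: pd.DataFrame  # strain, contig, group_id, start, end, strand
    homolog_distances: pd.DataFrame
    config: SimConfig


def _strain_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    reserves = [f"reserve{i + 1}" for i in range(config.n_reserves)]
    for i in range(config.n_serpentine):
        rows.append((f"S{i + 1:02d}", "serpentine", reserves[i % config.n_reserves]))
    for i in range(config.n_nonserpentine):
        rows.append((f"N{i + 1:02d}", "nonserpentine", reserves[i % config.n_reserves]))
    return pd.DataFrame(rows, columns=["strain", "soil", "reserve"])


def _balding_nichols(rng, p: np.ndarray, fst: float, k: int) -> np.ndarray:
    """Subgroup-specific frequencies around ancestral p (sites x k)."""
    p = np.clip(p, 1e-9, 1 - 1e-9)  # U-shaped spectra can hit 0/1 in float
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a[:, None], b[:, None], size=(p.size, k))


def simulate_population(config: SimConfig) -> tuple[PopulationDataset, SyntheticTruth]:
    """Generate a full synthetic dataset plus its ground truth.

    Core genes are present in every strain. Free accessory genes get an
    ancestral frequency from the Beta spectrum, diverged per admixture
    subgroup (Balding-Nichols with ``subgroup_fst``), and each strain carries
    a gene with probability equal to its admixture-weighted frequency.
    Planted cluster genes instead follow their ClusterSpec deterministically:
    round(assortment * n_serpentine) serpentine carriers and
    round(leak * n_nonserpentine) non-serpentine carriers, identical across
    the cluster's genes.
    """
    config.validate()
    strains = _strain_table(config)
    strain_ids = strains["strain"].tolist()
    n = len(strain_ids)

    # admixture loadings
    rng_q = _rng(config.seed, "admixture")
    q = rng_q.dirichlet([config.admixture_alpha] * config.n_subgroups, size=n)
    q_df = pd.DataFrame(
        q, index=strain_ids, columns=[f"pop{k + 1}" for k in range(config.n_subgroups)]
    )

    # gene inventory
    core_ids = [f"core{i:05d}" for i in range(config.core_size)]
    cluster_gene_ids: dict[str, list[str]] = {}
    for ci, spec in enumerate(config.planted_clusters):
        cid = f"cluster{chr(ord('A') + ci)}"
        cluster_gene_ids[cid] = [f"{cid}_g{j + 1:02d}" for j in range(spec.n_genes)]
    n_planted = sum(len(v) for v in cluster_gene_ids.values())
    n_free = config.accessory_pool - n_planted
    free_ids = [f"acc{i:05d}" for i in range(n_free)]

    rng_m = _rng(config.seed, "membership")
    a, b = config.freq_spectrum_shape
    ancestral = rng_m.beta(a, b, size=n_free)
    sub_freq = _balding_nichols(rng_m, ancestral, config.subgroup_fst, config.n_subgroups)
    carry_prob = q @ sub_freq.T  # strains x free genes
    free_mat = (rng_m.random((n, n_free)) < carry_prob).astype(np.int8)

    serp = strains.index[strains["soil"] == "serpentine"].to_numpy()
    nonserp = strains.index[strains["soil"] == "nonserpentine"].to_numpy()
    cluster_carriers: dict[str, list[str]] = {}
    planted_cols: dict[str, np.ndarray] = {}
    for (cid, genes), spec in zip(cluster_gene_ids.items(), config.planted_clusters):
        n_s = int(round(spec.assortment * len(serp)))
        n_n = int(round(spec.leak * len(nonserp)))
        pick_s = rng_m.choice(serp, size=n_s, replace=False) if n_s else np.array([], int)
        pick_n = rng_m.choice(nonserp, size=n_n, replace=False) if n_n else np.array([], int)
        idx = np.sort(np.concatenate([pick_s, pick_n])).astype(int)
        col = np.zeros(n, dtype=np.int8)
        col[idx] = 1
        cluster_carriers[cid] = [strain_ids[i] for i in idx]
        for g in genes:
            planted_cols[g] = col

    gene_order = core_ids + list(planted_cols) + free_ids
    presence = pd.DataFrame(
        np.concatenate(
            [
                np.ones((n, len(core_ids)), dtype=np.int8),
                np.stack([planted_cols[g] for g in planted_cols], axis=1)
                if planted_cols
                else np.zeros((n, 0), dtype=np.int8),
                free_mat,
            ],
            axis=1,
        ),
        index=strain_ids,
        columns=gene_order,
    )
    # a group must exist in >= 1 strain: drop never-observed free accessory genes
    presence = presence.loc[:, presence.sum(axis=0) > 0]

    # reference vs de-novo origin: core genes and half the accessory pool map
    # to the reference proteome, the rest are de novo
    origin = pd.Series("de-novo", index=presence.columns, dtype=object)
    origin.loc[[c for c in presence.columns if c.startswith("core")]] = "reference"
    free_present = [c for c in presence.columns if c.startswith("acc")]
    origin.loc[free_present[: len(free_present) // 2]] = "reference"

    # core-genome SNPs, subgroup-correlated
    rng_s = _rng(config.seed, "snp")
    p_anc = rng_s.uniform(0.05, 0.95, size=config.snp_sites)
    sub_p = _balding_nichols(rng_s, p_anc, config.subgroup_fst, config.n_subgroups)
    allele_prob = q @ sub_p.T
    snp_mat = (rng_s.random((n, config.snp_sites)) < allele_prob).astype(np.int8)
    bases = np.array(list("ACGT"))
    ref_i = rng_s.integers(0, 4, size=config.snp_sites)
    alt_i = (ref_i + rng_s.integers(1, 4, size=config.snp_sites)) % 4
    sites_per_gene = 50
    snp_info = pd.DataFrame(
        {
            "site": [f"snp{i:06d}" for i in range(config.snp_sites)],
            "gene_id": [f"core{i // sites_per_gene:05d}" for i in range(config.snp_sites)],
            "column": [(i % sites_per_gene) * 6 + 3 for i in range(config.snp_sites)],
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        }
    )
    snp = pd.DataFrame(snp_mat, index=strain_ids, columns=snp_info["site"].tolist())

    # ground truth
    causal: set[str] = set()
    effects: dict[str, float] = {}
    for (cid, genes), spec in zip(cluster_gene_ids.items(), config.planted_clusters):
        if spec.causal:
            causal.update(genes)
            for g in genes:
                effects[g] = config.phenotype_effect
    truth = SyntheticTruth(
        causal_gene_ids=causal,
        strain_subgroup_loadings=q_df,
        true_effects=effects,
        planted_cluster_coords={},
        cluster_genes=cluster_gene_ids,
        cluster_carriers=cluster_carriers,
    )

    phenotypes = simulate_phenotypes(truth, config)
    phenotypes = phenotypes.merge(strains, on="strain")

    layouts = fragment_genomes(presence, truth, config)
    for cid in cluster_gene_ids:
        coords: dict[str, tuple[str, int, int]] = {}
        sub = layouts[layouts["group_id"].isin(cluster_gene_ids[cid])]
        for strain, grp in sub.groupby("strain"):
            coords[strain] = (
                grp["contig"].iloc[0],
                int(grp["start"].min()),
                int(grp["end"].max()),
            )
        truth.planted_cluster_coords[cid] = coords

    accessory_ids = [c for c in presence.columns if not c.startswith("core")]
    homolog = simulate_homolog_distances(
        presence[accessory_ids], sorted(causal), config
    )

    dataset = PopulationDataset(
        strains=strains,
        presence=presence,
        group_origin=origin,
        snp=snp,
        snp_info=snp_info,
        phenotypes=phenotypes,
        q_matrix=q_df,
        layouts=layouts,
        homolog_distances=homolog,
        config=config,
    )
    return dataset, truth


def simulate_phenotypes(truth: SyntheticTruth, config: SimConfig) -> pd.DataFrame:
    """OD600 growth in high- and low-nickel media.

    High-Ni growth is baseline + one ``phenotype_effect`` per causal cluster
    carried + ``structure_effect`` times the first subgroup loading +
    Gaussian(0, phenotype_sd) noise. Low-Ni growth keeps the structure term
    and noise but has no causal term.
    """
    q = truth.strain_subgroup_loadings
    strain_ids = q.index.tolist()
    rng = _rng(config.seed, "phenotype")
    causal_term = np.zeros(len(strain_ids))
    carrier = {s: 0.0 for s in strain_ids}
    for cid, genes in truth.cluster_genes.items():
        if not genes or genes[0] not in truth.causal_gene_ids:
            continue
        for s in truth.cluster_carriers[cid]:
            carrier[s] += config.phenotype_effect
    causal_term = np.array([carrier[s] for s in strain_ids])
    structure_term = config.structure_effect * q.iloc[:, 0].to_numpy()
    high = (
        config.baseline_high_ni
        + causal_term
        + structure_term
        + rng.normal(0.0, config.phenotype_sd, size=len(strain_ids))
    )
    low = (
        config.baseline_low_ni
        + structure_term
        + rng.normal(0.0, config.phenotype_sd, size=len(strain_ids))
    )
    return pd.DataFrame(
        {
            "strain": strain_ids,
            "growth_highNi": np.clip(high, 0.0, None),
            "growth_lowNi": np.clip(low, 0.0, None),
        }
    )


def _cluster_layout_lengths(spec: ClusterSpec, gene_length: int) -> tuple[int, int]:
    """(gene length, intergenic gap) packing n_genes into span_bp."""
    glen = min(gene_length, spec.span_bp // spec.n_genes - 10)
    glen = max(glen, 90)
    total_genes = glen * spec.n_genes
    if total_genes > spec.span_bp:
        raise ValueError(
            f"span {spec.span_bp} too small for {spec.n_genes} genes of {glen} bp"
        )
    if spec.n_genes == 1:
        return glen, 0
    # spread genes to occupy the configured span (minus one trailing gap)
    gap = (spec.span_bp - total_genes) // (spec.n_genes - 1)
    return glen, max(gap, 1)


def fragment_genomes(
    presence: pd.DataFrame, truth: SyntheticTruth, config: SimConfig
) -> pd.DataFrame:
    """Lay each strain's gene complement onto draft-genome-like contigs.

    A single canonical gene order is drawn once and shared by all strains
    (each strain's layout is the canonical order restricted to its genes),
    with every planted cluster kept as one contiguous block packed within its
    ``span_bp`` on a single contig per carrier. Coordinates are 1-based
    inclusive GFF3-style, forward strand, non-overlapping. With
    ``shuffle_noncluster`` the order of non-cluster genes is permuted
    independently per strain, leaving cluster blocks intact.
    """
    config.validate()
    rng = _rng(config.seed, "layout")
    cluster_of: dict[str, str] = {}
    for cid, genes in truth.cluster_genes.items():
        for g in genes:
            cluster_of[g] = cid

    all_genes = list(presence.columns)
    noncluster = [g for g in all_genes if g not in cluster_of]
    order = list(rng.permutation(noncluster))
    # insert each cluster block at a random position between non-cluster genes
    blocks = [truth.cluster_genes[cid] for cid in truth.cluster_genes]
    insert_at = sorted(rng.integers(0, len(order) + 1, size=len(blocks)), reverse=True)
    tokens: list[object] = list(order)
    for pos, block in zip(insert_at, blocks):
        tokens.insert(pos, tuple(block))

    specs = {
        f"cluster{chr(ord('A') + i)}": s for i, s in enumerate(config.planted_clusters)
    }
    gene_len = {
        g: int(l)
        for g, l in zip(
            noncluster,
            np.clip(
                rng.normal(config.gene_length_bp, config.gene_length_bp / 6, len(noncluster)),
                150,
                None,
            ),
        )
    }
    rows: list[tuple] = []
    for strain in presence.index:
        present = set(presence.columns[presence.loc[strain].to_numpy() == 1])
        strain_tokens: list[object] = []
        for t in tokens:
            if isinstance(t, tuple):
                block = [g for g in t if g in present]
                if block:
                    strain_tokens.append(tuple(block))
            elif t in present:
                strain_tokens.append(t)
        if config.shuffle_noncluster:
            single = [t for t in strain_tokens if not isinstance(t, tuple)]
            perm = list(rng.permutation(single))
            it = iter(perm)
            strain_tokens = [t if isinstance(t, tuple) else next(it) for t in strain_tokens]

        # split into contigs without breaking cluster blocks
        contig_sizes_left = max(1, int(rng.poisson(config.contig_mean_genes)))
        contig_idx, genes_in_contig, pos = 1, 0, 0
        for t in strain_tokens:
            block = list(t) if isinstance(t, tuple) else [t]
            if genes_in_contig > 0 and genes_in_contig + 1 > contig_sizes_left:
                contig_idx += 1
                genes_in_contig, pos = 0, 0
                contig_sizes_left = max(1, int(rng.poisson(config.contig_mean_genes)))
            contig = f"{strain}_ctg{contig_idx:03d}"
            if isinstance(t, tuple):
                cid = cluster_of[block[0]]
                glen, gap = _cluster_layout_lengths(specs[cid], config.gene_length_bp)
                start = pos + 1 + int(rng.exponential(config.intergenic_bp)) + 1
                for g in block:
                    end = start + glen - 1
                    rows.append((strain, contig, g, start, end, "+"))
                    pos = end
                    start = end + gap + 1
                genes_in_contig += len(block)
            else:
                start = pos + 1 + int(rng.exponential(config.intergenic_bp)) + 1
                end = start + gene_len[t] - 1
                rows.append((strain, contig, t, start, end, "+"))
                pos = end
                genes_in_contig += 1
    layouts = pd.DataFrame(
        rows, columns=["strain", "contig", "group_id", "start", "end", "strand"]
    )
    return layouts.sort_values(["strain", "contig", "start"], kind="stable").reset_index(
        drop=True
    )


def simulate_homolog_distances(
    accessory: pd.DataFrame,
    candidate_ids: Sequence[str],
    config: SimConfig,
) -> pd.DataFrame:
    """Nearest-homolog 16S distance per accessory gene.

    Non-candidates draw from a Beta(2, 28) base distribution (mean ~0.067
    nucleotide divergence, the scale of between-genus 16S distances);
    candidate genes draw from the same base shifted upward by
    ``homolog_shift``, emulating acquisition from more distant donors.
    """
    candidate_ids = list(candidate_ids)
    genes = list(accessory.columns)
    unknown = set(candidate_ids) - set(genes)
    if unknown:
        raise ValueError(f"candidate ids not in accessory matrix: {sorted(unknown)[:5]}")
    if set(candidate_ids) == set(genes):
        raise ValueError(
            "every accessory gene is a candidate: no reference distribution remains"
        )
    rng = _rng(config.seed, "homolog")
    is_cand = np.array([g in set(candidate_ids) for g in genes])
    base = rng.beta(2.0, 28.0, size=len(genes))
    dist = np.clip(base + np.where(is_cand, config.homolog_shift, 0.0), 0.0, 1.0)
    return pd.DataFrame(
        {
            "group_id": genes,
            "closest_lineage": [f"lineage{rng.integers(0, 500):03d}" for _ in genes],
            "distance_16S": dist,
            "candidate_flag": is_cand,
            "fdr_tier": np.where(is_cand, 1, -1),  # -1 = none
        }
    )


def simulate_hit_tables(
    dataset: PopulationDataset,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Synthetic BLAST-style hit tables consistent with the true matrix.

    Purely synthetic plumbing for round-trip testing of the orthology
    pipeline: genes in reference-origin groups hit protein ``ref_<group>`` of
    the reference proteome; de-novo genes hit their orthologs in every other
    strain carrying the group. Gene instances are named ``<strain>|<group>``.
    Emitted scores comfortably pass the default hit filters.
    """
    rng = _rng(dataset.config.seed, "hits")
    presence = dataset.presence
    origin = dataset.group_origin
    ref_rows = []
    for gene in presence.columns[origin.loc[presence.columns] == "reference"]:
        for strain in presence.index[presence[gene] == 1]:
            qlen = 300
            ref_rows.append(
                (
                    f"{strain}|{gene}",
                    f"ref_{gene}",
                    float(rng.uniform(60, 95)),
                    int(qlen * rng.uniform(0.85, 1.0)),
                    qlen,
                    1e-50,
                    float(rng.uniform(300, 600)),
                )
            )
    cols = ["query_id", "subject_id", "percent_identity", "alignment_length",
            "query_length", "evalue", "bitscore"]
    reference_hits = pd.DataFrame(ref_rows, columns=cols)

    denovo = presence.columns[origin.loc[presence.columns] == "de-novo"]
    pairwise: dict[tuple[str, str], pd.DataFrame] = {}
    strains = presence.index.tolist()
    carriers = {g: set(presence.index[presence[g] == 1]) for g in denovo}
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            rows_ab, rows_ba = [], []
            for g in denovo:
                if a in carriers[g] and b in carriers[g]:
                    ident = float(rng.uniform(80, 99))
                    score = float(rng.uniform(400, 700))
                    rows_ab.append((f"{a}|{g}", f"{b}|{g}", ident, 280, 300, 1e-60, score))
                    rows_ba.append((f"{b}|{g}", f"{a}|{g}", ident, 280, 300, 1e-60, score))
            pairwise[(a, b)] = pd.DataFrame(rows_ab, columns=cols)
            pairwise[(b, a)] = pd.DataFrame(rows_ba, columns=cols)
    return reference_hits, pairwise


@dataclass
class EfficacyReport:
    """Outcome of the gene-dropout mis-partition simulation."""

    dropout_rate: float
    n_strains: int
    n_reps: int
    core_to_accessory_rate: float  # mean over reps
    per_rep_rates: list[float]
    accessory_freq_distortion: float  # mean |observed - true| carrier frequency

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_accessory_identification(
    matrix: pd.DataFrame, dropout_rate: float, n_reps: int, seed: int
) -> EfficacyReport:
    """Quantify core/accessory mis-partition under per-gene dropout.

    Each replicate hides every present gene call independently with
    probability ``dropout_rate`` (a draft-assembly miss), re-runs the
    core/accessory partition over all strains, and records the fraction of
    truly core genes called accessory plus the mean absolute distortion of
    accessory carrier frequencies. A core gene survives as core only if no
    strain drops it, so the per-gene misclassification probability is
    essentially 1 - (1 - d)^S.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    strains = list(matrix.index)
    true_core, true_acc = pangenome.partition_core_accessory(matrix, strains)
    true_freq = matrix[true_acc].mean(axis=0) if true_acc else pd.Series(dtype=float)
    rates, distortions = [], []
    vals = matrix.to_numpy()
    for _ in range(n_reps):
        keep = rng.random(vals.shape) >= dropout_rate
        observed = pd.DataFrame(
            vals * keep, index=matrix.index, columns=matrix.columns
        )
        obs_core, obs_acc = pangenome.partition_core_accessory(observed, strains)
        obs_acc_set = set(obs_acc)
        if true_core:
            rates.append(sum(g in obs_acc_set for g in true_core) / len(true_core))
        else:
            rates.append(0.0)
        if true_acc:
            obs_freq = observed[true_acc].mean(axis=0)
            distortions.append(float((obs_freq - true_freq).abs().mean()))
        else:
            distortions.append(0.0)
    return EfficacyReport(
        dropout_rate=dropout_rate,
        n_strains=len(strains),
        n_reps=n_reps,
        core_to_accessory_rate=float(np.mean(rates)),
        per_rep_rates=[float(r) for r in rates],
        accessory_freq_distortion=float(np.mean(distortions)),
    )


def core_alignments(dataset: PopulationDataset, alignment_length: int = 300):
    """Yield (gene_id, {strain: sequence}) core-gene alignments.

    Each pseudo-gene alignment has a deterministic monomorphic background with
    the dataset's SNP sites embedded at their recorded columns, so the SNP
    caller can be round-tripped against the emitted genotype matrix.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(dataset.config.seed), spawn_key=(99,))
    )
    bases = np.array(list("ACGT"))
    for gene_id, info in dataset.snp_info.groupby("gene_id", sort=True):
        background = bases[rng.integers(0, 4, size=alignment_length)]
        seqs = {}
        for strain in dataset.snp.index:
            arr = background.copy()
            for _, row in info.iterrows():
                allele = dataset.snp.loc[strain, row["site"]]
                arr[row["column"] - 1] = row["alt"] if allele == 1 else row["ref"]
            seqs[strain] = "".join(arr)
        yield gene_id, seqs
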