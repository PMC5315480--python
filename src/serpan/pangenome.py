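"""Ortholog groups, presence/absence matrices and SNP calling.

Turns per-strain BLAST-style hit tables into ortholog groups (reference-gene
assignment plus single-linkage closure over reciprocal best hits), builds the
strains x groups presence/absence matrix, partitions core from accessory
genes per strain subset, and calls SNPs from core-gene multiple alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "query_length",
    "evalue",
    "bitscore",
]


def filter_hits(
    hits: pd.DataFrame,
    min_overlap: float = 0.80,
    max_evalue: float = 1e-20,
    min_identity: float = 50.0,
    overlap_denominator: str = "query",
) -> pd.DataFrame:
    """Retain hits passing all three thresholds, each strict.

    Overlap is alignment_length / query_length by default (the denominator is
    configurable to subject_length if that column is present). A hit is kept
    iff overlap > min_overlap AND evalue < max_evalue AND identity >
    min_identity.
    """
    if hits.empty:
        return hits.copy()
    denom_col = "query_length" if overlap_denominator == "query" else "subject_length"
    if denom_col not in hits.columns or hits[denom_col].isna().any():
        bad = (
            hits.index[hits[denom_col].isna()].tolist()
            if denom_col in hits.columns
            else list(hits.index)
        )
        raise ValueError(f"missing {denom_col} for hit records at index {bad[:10]}")
    overlap = hits["alignment_length"] / hits[denom_col]
    keep = (
        (overlap > min_overlap)
        & (hits["evalue"] < max_evalue)
        & (hits["percent_identity"] > min_identity)
    )
    return hits.loc[keep].copy()


def _best_hits(hits: pd.DataFrame) -> tuple[dict[str, str], set[str]]:
    """Unique best subject per query; returns (best map, ambiguous queries).

    Best = max bitscore, ties broken by min E-value, then lexicographically
    smallest subject id. A query whose top two hits tie on both bitscore and
    E-value is resolved deterministically but flagged ambiguous.
    """
    best: dict[str, str] = {}
    ambiguous: set[str] = set()
    if hits.empty:
        return best, ambiguous
    ordered = hits.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    for query, grp in ordered.groupby("query_id", sort=False):
        best[query] = grp["subject_id"].iloc[0]
        if len(grp) > 1:
            top, second = grp.iloc[0], grp.iloc[1]
            if (
                top["bitscore"] == second["bitscore"]
                and top["evalue"] == second["evalue"]
            ):
                ambiguous.add(query)
                logger.warning("ambiguous best hit for %s; lexicographic winner kept", query)
    return best, ambiguous


def reciprocal_best_hits(
    hits_a_to_b: pd.DataFrame, hits_b_to_a: pd.DataFrame
) -> set[tuple[str, str]]:
    """Pairs (a, b) where each is the other's unique best hit."""
    best_ab, _ = _best_hits(hits_a_to_b)
    best_ba, _ = _best_hits(hits_b_to_a)
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


@dataclass
class OrthologGroups:
    """Gene -> group assignment with group provenance."""

    assignments: pd.DataFrame  # gene_id, group_id, origin, strain

    @property
    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.assignments.groupby("group_id", sort=True)

    def group_ids(self) -> list[str]:
        return sorted(self.assignments["group_id"].unique())


def _strain_of(gene_id: str) -> str:
    # gene instances are "<strain>|<local id>"
    return gene_id.split("|", 1)[0]


def build_ortholog_groups(
    rbh_pairs: Iterable[tuple[str, str]],
    reference_hits: pd.DataFrame,
    all_genes: Iterable[str] | None = None,
) -> OrthologGroups:
    """Group genes by shared reference protein, then by RBH closure.

    Genes whose (filtered) best hit is the same reference protein share that
    protein's group; the remaining genes are grouped by single-linkage
    closure over the reciprocal-best-hit graph. A gene claimed by both a
    reference group and a de-novo closure stays with the reference group.
    Genes listed in ``all_genes`` but absent from both sources become
    singleton de-novo groups. Within a group, one gene per strain is
    enforced (best reference bitscore, else lexicographic, wins).
    """
    best_ref, _ = _best_hits(reference_hits)
    ref_score: dict[str, float] = {}
    if not reference_hits.empty:
        ref_score = reference_hits.groupby("query_id")["bitscore"].max().to_dict()

    rows: list[tuple[str, str, str]] = []
    for gene, protein in best_ref.items():
        rows.append((gene, f"ref|{protein}", "reference"))
    ref_assigned = set(best_ref)

    graph = nx.Graph()
    for a, b in rbh_pairs:
        if a in ref_assigned or b in ref_assigned:
            if (a in ref_assigned) != (b in ref_assigned):
                logger.info(
                    "RBH edge (%s, %s) touches a reference-assigned gene; "
                    "reference assignment wins",
                    a,
                    b,
                )
            continue
        graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    if all_genes is not None:
        placed = ref_assigned | set(graph.nodes)
        singletons = sorted(set(all_genes) - placed)
        components.extend({g} for g in singletons)
        components.sort(key=min)
    for i, comp in enumerate(components):
        gid = f"denovo|{i:05d}"
        for gene in sorted(comp):
            rows.append((gene, gid, "de-novo"))

    df = pd.DataFrame(rows, columns=["gene_id", "group_id", "origin"])
    df["strain"] = df["gene_id"].map(_strain_of)
    # in-paralog resolution: one gene per strain per group
    df["_score"] = df["gene_id"].map(lambda g: ref_score.get(g, 0.0))
    df = df.sort_values(
        ["group_id", "strain", "_score", "gene_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    dup = df.duplicated(["group_id", "strain"], keep="first")
    if dup.any():
        logger.info("dropped %d in-paralog assignments (best bitscore kept)", dup.sum())
    df = df.loc[~dup].drop(columns="_score").reset_index(drop=True)
    return OrthologGroups(assignments=df)


def presence_absence(
    groups: OrthologGroups, strains: Sequence[str] | None = None
) -> pd.DataFrame:
    """Strains x groups binary matrix from group assignments."""
    df = groups.assignments
    mat = (
        df.assign(present=1)
        .pivot_table(index="strain", columns="group_id", values="present", fill_value=0)
        .astype(np.int8)
    )
    if strains is not None:
        mat = mat.reindex(list(strains), fill_value=0).astype(np.int8)
        mat = mat.loc[:, mat.sum(axis=0) > 0]
    mat.columns.name = None
    mat.index.name = None
    return mat


def partition_core_accessory(
    matrix: pd.DataFrame, strain_subset: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Core (all-present) vs accessory (present in some, absent in some).

    Columns absent from every subset strain belong to neither compartment:
    they are not part of the subset's pan-genome. Raises if the subset is
    empty, contains unknown strains, or has an empty pan-genome.
    """
    subset = list(strain_subset)
    if not subset:
        raise ValueError("strain subset is empty")
    missing = set(subset) - set(matrix.index)
    if missing:
        raise ValueError(f"strains not in matrix: {sorted(missing)}")
    sub = matrix.loc[subset]
    counts = sub.sum(axis=0)
    n = len(subset)
    core = counts.index[counts == n].tolist()
    accessory = counts.index[(counts >= 1) & (counts < n)].tolist()
    if not core and not accessory:
        raise ValueError("subset pan-genome is empty: no gene present in any strain")
    return core, accessory


def pan_core_counts(
    matrix: pd.DataFrame, named_subsets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Pan- and core-genome sizes for each named strain subset."""
    rows = []
    for name, subset in named_subsets.items():
        core, accessory = partition_core_accessory(matrix, subset)
        rows.append((name, len(subset), len(core) + len(accessory), len(core)))
    return pd.DataFrame(rows, columns=["subset", "n_strains", "pan_size", "core_size"])


def gene_frequency_spectrum(matrix: pd.DataFrame) -> pd.Series:
    """Number of genes at each occupancy 1..S (how many strains carry them)."""
    occupancy = matrix.sum(axis=0).astype(int)
    s = len(matrix.index)
    counts = occupancy.value_counts().reindex(range(1, s + 1), fill_value=0)
    counts.index.name = "n_strains"
    counts.name = "n_genes"
    return counts


@dataclass(frozen=True)
class SnpSite:
    gene_id: str
    alignment_column: int  # 1-based
    alleles: Mapping[str, str]
    n_alleles: int

    @property
    def biallelic(self) -> bool:
        return self.n_alleles == 2


_VALID_BASES = frozenset("ACGT")


def call_snps_from_alignment(
    alignment: Mapping[str, str], strain_subset: Sequence[str], gene_id: str = "gene"
) -> list[SnpSite]:
    """Polymorphic columns among the subset rows of one gene alignment.

    Columns containing a gap or ambiguity character in any subset row are
    skipped entirely (complete-column rule, keeps the genotype matrix
    rectangular). Multi-allelic sites are emitted and flagged; downstream
    association keeps only biallelic sites.
    """
    seqs = dict(alignment)
    missing = set(strain_subset) - set(seqs)
    if missing:
        raise ValueError(f"strains missing from alignment: {sorted(missing)}")
    lengths = {len(seqs[s]) for s in strain_subset}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    sites: list[SnpSite] = []
    for col in range(length):
        bases = {s: seqs[s][col].upper() for s in strain_subset}
        observed = set(bases.values())
        if not observed <= _VALID_BASES:
            continue  # gap/ambiguity rule
        if len(observed) >= 2:
            sites.append(
                SnpSite(
                    gene_id=gene_id,
                    alignment_column=col + 1,
                    alleles=bases,
                    n_alleles=len(observed),
                )
            )
    return sites


def snp_matrix_from_sites(
    sites: Sequence[SnpSite], strains: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(strains x sites 0/1 matrix, site info) for biallelic coding.

    Allele 1 is the lexicographically larger base; multi-allelic sites are
    carried in the info table with n_alleles > 2 and coded NaN in the matrix.
    """
    data = {}
    info_rows = []
    for site in sites:
        sid = f"{site.gene_id}:{site.alignment_column}"
        alleles = sorted(set(site.alleles.values()))
        info_rows.append((sid, site.gene_id, site.alignment_column, site.n_alleles))
        if site.n_alleles == 2:
            ref, alt = alleles
            data[sid] = [1 if site.alleles[s] == alt else 0 for s in strains]
        else:
            data[sid] = [np.nan] * len(strains)
    matrix = pd.DataFrame(data, index=list(strains))
    info = pd.DataFrame(info_rows, columns=["site", "gene_id", "column", "n_alleles"])
    return matrix, info
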