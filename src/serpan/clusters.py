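"""Positional clustering of candidate genes on draft-genome contigs.

A cluster is seeded by a run of at least ``min_tandem`` consecutive candidate
genes on one contig and grown outward, absorbing any further candidate whose
proximal coordinate lies within ``gap_bp`` of the current cluster edge
(intervening non-candidates are spanned but not members), iterated to a
fixpoint; clusters brought into contact are merged. Families of matching
clusters across strains are formed by single-linkage on candidate-membership
Jaccard similarity, with gene-order conservation scored by longest common
subsequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CandidateCluster",
    "call_clusters",
    "soil_assortment",
    "match_clusters_across_strains",
    "cluster_summary",
]


@dataclass
class CandidateCluster:
    strain: str
    contig: str
    members: list[str]  # candidate group_ids, ordered by start coordinate
    start: int
    end: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def n_candidates(self) -> int:
        return len(self.members)


def _validate_contig(genes: pd.DataFrame) -> None:
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    if np.any(np.diff(starts) < 0):
        raise ValueError("contig gene map is not sorted by start coordinate")
    if np.any(starts[1:] <= ends[:-1]):
        raise ValueError("overlapping genes on contig")


def _clusters_on_contig(
    genes: pd.DataFrame, min_tandem: int, gap_bp: int
) -> list[tuple[set[int], int, int]]:
    """(member row indices, start, end) clusters for one sorted contig."""
    cand = genes["candidate"].to_numpy().astype(bool)
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    n = len(genes)

    # seed: maximal runs of consecutive candidates of length >= min_tandem
    clusters: list[tuple[set[int], int, int]] = []
    i = 0
    while i < n:
        if cand[i]:
            j = i
            while j + 1 < n and cand[j + 1]:
                j += 1
            if j - i + 1 >= min_tandem:
                members = set(range(i, j + 1))
                clusters.append((members, int(starts[i]), int(ends[j])))
            i = j + 1
        else:
            i += 1

    cand_idx = np.flatnonzero(cand)
    changed = True
    while changed:
        changed = False
        for k, (members, lo, hi) in enumerate(clusters):
            for idx in cand_idx:
                if idx in members:
                    continue
                s, e = int(starts[idx]), int(ends[idx])
                inside = s >= lo and e <= hi
                near_right = s > hi and s - hi <= gap_bp
                near_left = e < lo and lo - e <= gap_bp
                if inside or near_right or near_left:
                    members.add(int(idx))
                    clusters[k] = (members, min(lo, s), max(hi, e))
                    lo, hi = clusters[k][1], clusters[k][2]
                    changed = True
        # merge clusters sharing members or overlapping spans
        merged: list[tuple[set[int], int, int]] = []
        for members, lo, hi in sorted(clusters, key=lambda c: c[1]):
            if merged and (members & merged[-1][0] or lo <= merged[-1][2]):
                prev = merged[-1]
                merged[-1] = (prev[0] | members, min(prev[1], lo), max(prev[2], hi))
                changed = changed or (members - prev[0] != set())
            else:
                merged.append((members, lo, hi))
        clusters = merged
    return clusters


def call_clusters(
    contig_map: pd.DataFrame,
    candidate_ids: Iterable[str],
    min_tandem: int = 4,
    gap_bp: int = 10_000,
) -> list[CandidateCluster]:
    """Call candidate clusters on every contig of every strain.

    ``contig_map`` needs columns strain, contig, group_id, start, end
    (1-based inclusive, sorted by start within each contig, non-overlapping).
    The gap rule is inclusive: a candidate exactly ``gap_bp`` beyond the edge
    is still absorbed.
    """
    candidate_set = set(candidate_ids)
    out: list[CandidateCluster] = []
    for (strain, contig), genes in contig_map.groupby(["strain", "contig"], sort=True):
        genes = genes.reset_index(drop=True)
        _validate_contig(genes)
        genes = genes.assign(candidate=genes["group_id"].isin(candidate_set))
        for members, lo, hi in _clusters_on_contig(genes, min_tandem, gap_bp):
            ordered = genes.loc[sorted(members)].sort_values("start")
            out.append(
                CandidateCluster(
                    strain=strain,
                    contig=contig,
                    members=ordered["group_id"].tolist(),
                    start=lo,
                    end=hi,
                )
            )
    return out


def soil_assortment(
    carrier_strains: Iterable[str], soil_labels: pd.Series
) -> dict:
    """Habitat assortment of a matched cluster across strains.

    "perfect": carriers are exactly the serpentine strains; "serpentine_only":
    carriers are a subset of serpentine strains.
    """
    carriers = set(carrier_strains)
    unknown = carriers - set(soil_labels.index)
    if unknown:
        raise ValueError(f"carrier strains without soil labels: {sorted(unknown)}")
    serpentine = set(soil_labels.index[soil_labels == "serpentine"])
    n_s = len(carriers & serpentine)
    n_n = len(carriers - serpentine)
    return {
        "n_serpentine_carriers": n_s,
        "n_nonserpentine_carriers": n_n,
        "serpentine_only": carriers <= serpentine and bool(carriers),
        "perfect": carriers == serpentine and bool(carriers),
    }


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    dp = [0] * (len(b) + 1)
    for x in a:
        prev = 0
        for j, y in enumerate(b, start=1):
            cur = dp[j]
            dp[j] = prev + 1 if x == y else max(dp[j], dp[j - 1])
            prev = cur
    return dp[-1]


@dataclass
class ClusterFamily:
    family_id: str
    clusters: list[CandidateCluster]
    union_members: list[str] = field(default_factory=list)
    order_conservation: float = 1.0  # mean pairwise LCS / min length

    @property
    def carrier_strains(self) -> list[str]:
        return sorted({c.strain for c in self.clusters})

    @property
    def max_span_bp(self) -> int:
        return max(c.span_bp for c in self.clusters)


def match_clusters_across_strains(
    clusters: Sequence[CandidateCluster], min_jaccard: float = 0.5
) -> list[ClusterFamily]:
    """Single-linkage families of clusters with similar candidate content."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    sets = [set(c.members) for c in clusters]
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            union = sets[i] | sets[j]
            if union and len(sets[i] & sets[j]) / len(union) >= min_jaccard:
                graph.add_edge(i, j)
    families = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for fi, comp in enumerate(comps):
        members = [clusters[i] for i in sorted(comp)]
        union: set[str] = set()
        for c in members:
            union |= set(c.members)
        pair_scores = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i].members, members[j].members
                pair_scores.append(_lcs_length(a, b) / min(len(a), len(b)))
        families.append(
            ClusterFamily(
                family_id=f"family{fi + 1:02d}",
                clusters=members,
                union_members=sorted(union),
                order_conservation=float(np.mean(pair_scores)) if pair_scores else 1.0,
            )
        )
    return families


def cluster_summary(
    families: Sequence[ClusterFamily],
    association_results: pd.DataFrame | None = None,
    presence: pd.DataFrame | None = None,
    soil_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-family report: size, span, Bonferroni and perfect-assortment counts."""
    bonferroni: set[str] = set()
    if association_results is not None and "bonferroni_sig" in association_results:
        bonferroni = set(
            association_results.loc[
                association_results["bonferroni_sig"], "variant_id"
            ]
        )
    serpentine: set[str] = set()
    if soil_labels is not None:
        serpentine = set(soil_labels.index[soil_labels == "serpentine"])
    rows = []
    for fam in families:
        n_perfect = 0
        if presence is not None and soil_labels is not None:
            for g in fam.union_members:
                if g in presence.columns:
                    carriers = set(presence.index[presence[g] == 1])
                    if carriers == serpentine:
                        n_perfect += 1
        rows.append(
            (
                fam.family_id,
                len(fam.clusters),
                len(fam.carrier_strains),
                len(fam.union_members),
                fam.max_span_bp,
                len(set(fam.union_members) & bonferroni),
                n_perfect,
                fam.order_conservation,
                ",".join(fam.carrier_strains),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "n_clusters",
            "n_strains",
            "n_candidates",
            "max_span_bp",
            "n_bonferroni",
            "n_perfectly_assorting",
            "order_conservation",
            "carrier_strains",
        ],
    )
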