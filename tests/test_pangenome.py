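"""Hit filtering, orthology, core/accessory partition, SNP calling."""

import numpy as np
import pandas as pd
import pytest

from serpan import pangenome, synthio
from serpan.pangenome import HIT_COLUMNS


def _hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


class TestFilterHits:
    def test_thresholds_are_strict(self):
        hits = _hits(
            [
                ("q1", "s1", 60.0, 255, 300, 1e-25, 100.0),  # overlap 0.85: keep
                ("q2", "s1", 60.0, 240, 300, 1e-25, 100.0),  # overlap 0.80: drop
                ("q3", "s1", 50.0, 255, 300, 1e-25, 100.0),  # identity 50: drop
                ("q4", "s1", 60.0, 255, 300, 1e-20, 100.0),  # evalue 1e-20: drop
            ]
        )
        kept = pangenome.filter_hits(hits)
        assert kept["query_id"].tolist() == ["q1"]

    def test_empty_input_and_idempotence(self):
        empty = _hits([])
        assert pangenome.filter_hits(empty).empty
        hits = _hits([("q1", "s1", 60.0, 255, 300, 1e-25, 100.0)])
        once = pangenome.filter_hits(hits)
        twice = pangenome.filter_hits(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_query_length_is_an_error(self):
        hits = _hits([("q1", "s1", 60.0, 255, np.nan, 1e-25, 100.0)])
        with pytest.raises(ValueError, match="query_length"):
            pangenome.filter_hits(hits)


class TestReciprocalBestHits:
    def test_mutual_best_pairs(self):
        ab = _hits([("a", "b", 90, 280, 300, 1e-50, 500)])
        ba = _hits([("b", "a", 90, 280, 300, 1e-50, 500)])
        assert pangenome.reciprocal_best_hits(ab, ba) == {("a", "b")}

    def test_non_mutual_best_is_excluded(self):
        ab = _hits([("a", "b", 90, 280, 300, 1e-50, 500)])
        ba = _hits(
            [
                ("b", "a", 90, 280, 300, 1e-50, 400),
                ("b", "a2", 90, 280, 300, 1e-50, 500),
            ]
        )
        assert pangenome.reciprocal_best_hits(ab, ba) == set()

    def test_tie_broken_lexicographically(self):
        ab = _hits(
            [
                ("a", "b2", 90, 280, 300, 1e-50, 500),
                ("a", "b1", 90, 280, 300, 1e-50, 500),
            ]
        )
        ba = _hits([("b1", "a", 90, 280, 300, 1e-50, 500)])
        assert pangenome.reciprocal_best_hits(ab, ba) == {("a", "b1")}


class TestBuildOrthologGroups:
    def test_single_linkage_closure(self):
        groups = pangenome.build_ortholog_groups(
            [("s1|a", "s2|b"), ("s2|b", "s3|c")], _hits([])
        )
        ids = groups.assignments.set_index("gene_id")["group_id"]
        assert ids["s1|a"] == ids["s2|b"] == ids["s3|c"]

    def test_no_edges_gives_singleton_groups(self):
        groups = pangenome.build_ortholog_groups(
            [], _hits([]), all_genes=["s1|a", "s2|b"]
        )
        assert groups.assignments["group_id"].nunique() == 2
        assert pangenome.build_ortholog_groups([], _hits([])).assignments.empty

    def test_reference_assignment_wins_over_closure(self):
        ref = _hits([("s1|a", "prot1", 90, 280, 300, 1e-50, 500)])
        groups = pangenome.build_ortholog_groups([("s1|a", "s2|b")], ref)
        ids = groups.assignments.set_index("gene_id")["group_id"]
        assert ids["s1|a"] == "ref|prot1"
        assert "s2|b" not in ids.index  # edge dropped with the conflict

    def test_invariant_to_input_order(self):
        pairs = [("s1|a", "s2|b"), ("s2|b", "s3|c"), ("s4|d", "s5|e")]
        g1 = pangenome.build_ortholog_groups(pairs, _hits([]))
        g2 = pangenome.build_ortholog_groups(pairs[::-1], _hits([]))
        pd.testing.assert_frame_equal(
            g1.assignments.sort_values("gene_id").reset_index(drop=True),
            g2.assignments.sort_values("gene_id").reset_index(drop=True),
        )


class TestPartitionCoreAccessory:
    @pytest.fixture()
    def matrix(self):
        return pd.DataFrame(
            {
                "g_all": [1, 1, 1],
                "g_missing_one": [1, 1, 0],
                "g_one": [1, 0, 0],
                "g_absent_in_ab": [0, 0, 1],
            },
            index=["a", "b", "c"],
        )

    def test_definitions(self, matrix):
        core, accessory = pangenome.partition_core_accessory(matrix, ["a", "b", "c"])
        assert core == ["g_all"]
        assert set(accessory) == {"g_missing_one", "g_one", "g_absent_in_ab"}

    def test_compartments_partition_the_columns(self, matrix):
        core, accessory = pangenome.partition_core_accessory(matrix, ["a", "b"])
        absent = set(matrix.columns) - set(core) - set(accessory)
        assert absent == {"g_absent_in_ab"}
        assert not set(core) & set(accessory)

    def test_single_strain_subset_has_no_accessory(self, matrix):
        core, accessory = pangenome.partition_core_accessory(matrix, ["a"])
        assert set(core) == {"g_all", "g_missing_one", "g_one"}
        assert accessory == []

    def test_empty_subset_rejected(self, matrix):
        with pytest.raises(ValueError, match="empty"):
            pangenome.partition_core_accessory(matrix, [])


class TestPanCoreCounts:
    def test_two_strain_example(self):
        matrix = pd.DataFrame(
            {"g1": [1, 0], "g2": [1, 1], "g3": [0, 1]}, index=["a", "b"]
        )
        table = pangenome.pan_core_counts(matrix, {"both": ["a", "b"], "a": ["a"]})
        both = table.set_index("subset").loc["both"]
        assert both["pan_size"] == 3 and both["core_size"] == 1
        single = table.set_index("subset").loc["a"]
        assert single["pan_size"] == single["core_size"] == 2

    def test_monotone_over_nested_chains(self, small_dataset):
        ds, _ = small_dataset
        rng = np.random.default_rng(0)
        strains = list(ds.presence.index)
        for _ in range(5):
            order = list(rng.permutation(strains))
            chain = {f"k{k}": order[:k] for k in (1, 5, 10, 20, len(order))}
            table = pangenome.pan_core_counts(ds.presence, chain)
            assert table["pan_size"].is_monotonic_increasing
            assert (table["core_size"].diff().dropna() <= 0).all()


class TestGeneFrequencySpectrum:
    def test_identity_and_saturated_matrices(self):
        ident = pd.DataFrame(np.eye(2, dtype=int), index=["a", "b"], columns=["g1", "g2"])
        spec = pangenome.gene_frequency_spectrum(ident)
        assert spec[1] == 2 and spec[2] == 0
        ones = pd.DataFrame(np.ones((3, 4), dtype=int), index=list("abc"))
        spec = pangenome.gene_frequency_spectrum(ones)
        assert spec[3] == 4 and spec.sum() == 4


class TestCallSnps:
    def test_biallelic_gap_and_multiallelic_columns(self):
        aln = {"s1": "AAA", "s2": "A-C", "s3": "AAG", "s4": "AAG"}
        sites = pangenome.call_snps_from_alignment(aln, ["s1", "s2", "s3", "s4"])
        # col 1 monomorphic, col 2 has a gap, col 3 is multi-allelic A/C/G
        assert len(sites) == 1
        assert sites[0].alignment_column == 3
        assert sites[0].n_alleles == 3 and not sites[0].biallelic

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            pangenome.call_snps_from_alignment({"s1": "AAA", "s2": "AA"}, ["s1", "s2"])

    def test_alignment_round_trip_recovers_snp_matrix(self):
        cfg = synthio.SimConfig(seed=9, core_size=20, accessory_pool=60,
                                snp_sites=100, planted_clusters=())
        ds, _ = synthio.simulate_population(cfg)
        strains = list(ds.snp.index)
        recovered = {}
        for gene_id, seqs in synthio.core_alignments(ds):
            for site in pangenome.call_snps_from_alignment(seqs, strains, gene_id):
                info = ds.snp_info[
                    (ds.snp_info["gene_id"] == gene_id)
                    & (ds.snp_info["column"] == site.alignment_column)
                ]
                assert len(info) == 1
                row = info.iloc[0]
                recovered[row["site"]] = {
                    s: int(site.alleles[s] == row["alt"]) for s in strains
                }
        # every truly polymorphic emitted site is recovered with right genotypes
        truth_poly = ds.snp.columns[(ds.snp.sum(axis=0) > 0) & (ds.snp.sum(axis=0) < len(strains))]
        assert set(recovered) == set(truth_poly)
        for sid in truth_poly:
            assert recovered[sid] == ds.snp[sid].to_dict()


def test_dropout_free_hit_tables_round_trip_to_truth_matrix():
    cfg = synthio.SimConfig(seed=13, n_serpentine=5, n_nonserpentine=5,
                            core_size=30, accessory_pool=80, snp_sites=20,
                            planted_clusters=())
    ds, _ = synthio.simulate_population(cfg)
    ref_hits, pairwise = synthio.simulate_hit_tables(ds)
    ref_hits = pangenome.filter_hits(ref_hits)
    rbh = set()
    strains = list(ds.presence.index)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            rbh |= pangenome.reciprocal_best_hits(
                pangenome.filter_hits(pairwise[(a, b)]),
                pangenome.filter_hits(pairwise[(b, a)]),
            )
    all_genes = [
        f"{s}|{g}" for g in ds.presence.columns for s in ds.presence.index[ds.presence[g] == 1]
    ]
    groups = pangenome.build_ortholog_groups(rbh, ref_hits, all_genes=all_genes)
    matrix = pangenome.presence_absence(groups, strains)
    # map each reconstructed group back to the simulated gene it contains
    local = groups.assignments.copy()
    local["gene"] = local["gene_id"].str.split("|").str[1]
    assert (local.groupby("group_id")["gene"].nunique() == 1).all()
    renamed = matrix.rename(columns=local.set_index("group_id")["gene"].to_dict())
    pd.testing.assert_frame_equal(
        renamed.sort_index(axis=1),
        ds.presence.sort_index(axis=1).astype(np.int8),
        check_names=False,
    )
    # group partition matches truth perfectly (adjusted Rand index 1)
    from sklearn.metrics import adjusted_rand_score

    truth_labels = local["gene"].astype("category").cat.codes
    found_labels = local["group_id"].astype("category").cat.codes
    assert adjusted_rand_score(truth_labels, found_labels) == 1.0
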