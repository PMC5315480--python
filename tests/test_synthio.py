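"""Generator contracts: determinism, planted structure, spectra, dropout."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serpan import synthio
from serpan.synthio import ClusterSpec, SimConfig


def _single_cluster_config(**kw):
    base = dict(
        seed=11,
        core_size=40,
        accessory_pool=200,
        snp_sites=60,
        planted_clusters=(ClusterSpec(n_genes=13, span_bp=30_000),),
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulatePopulation:
    def test_same_seed_reproduces_outputs_exactly(self, small_config):
        ds1, t1 = synthio.simulate_population(small_config)
        ds2, t2 = synthio.simulate_population(small_config)
        pd.testing.assert_frame_equal(ds1.presence, ds2.presence)
        pd.testing.assert_frame_equal(ds1.snp, ds2.snp)
        pd.testing.assert_frame_equal(ds1.phenotypes, ds2.phenotypes)
        pd.testing.assert_frame_equal(ds1.layouts, ds2.layouts)
        pd.testing.assert_frame_equal(
            ds1.homolog_distances, ds2.homolog_distances
        )
        assert t1.causal_gene_ids == t2.causal_gene_ids
        # byte-identical serialization
        assert ds1.presence.to_csv() == ds2.presence.to_csv()

    def test_perfectly_assorting_cluster_is_forced(self):
        cfg = _single_cluster_config()
        ds, truth = synthio.simulate_population(cfg)
        assert len(truth.causal_gene_ids) == 13
        soil = ds.strains.set_index("strain")["soil"]
        for gene in truth.causal_gene_ids:
            carriers = set(ds.presence.index[ds.presence[gene] == 1])
            assert carriers == set(soil.index[soil == "serpentine"])

    def test_frequency_spectrum_is_u_shaped(self):
        cfg = SimConfig(seed=3, core_size=10, accessory_pool=2000, snp_sites=10,
                        planted_clusters=())
        ds, _ = synthio.simulate_population(cfg)
        acc = [c for c in ds.presence.columns if c.startswith("acc")]
        freq = ds.presence[acc].mean(axis=0)
        extreme = float(((freq < 0.1) | (freq > 0.9)).mean())
        middle = float(((freq >= 0.4) & (freq <= 0.6)).mean())
        assert extreme > middle
        # closed-form Beta(0.3, 0.3) tail mass, diluted by binomial sampling
        # and subgroup divergence; generous Monte-Carlo band
        rv = stats.beta(0.3, 0.3)
        assert abs(extreme - 2 * rv.cdf(0.1)) < 0.2

    def test_q_matrix_rows_sum_to_one(self, small_dataset):
        ds, truth = small_dataset
        np.testing.assert_allclose(ds.q_matrix.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            truth.strain_subgroup_loadings.sum(axis=1), 1.0, atol=1e-9
        )

    def test_rejects_planted_genes_exceeding_pool(self):
        with pytest.raises(ValueError, match="exceed accessory_pool"):
            SimConfig(
                accessory_pool=10,
                planted_clusters=(ClusterSpec(n_genes=13, span_bp=30_000),),
            ).validate()

    def test_subgroup_differentiation_grows_with_fst(self):
        def mean_abs_diff(fst):
            cfg = SimConfig(seed=5, core_size=10, accessory_pool=50,
                            snp_sites=800, subgroup_fst=fst, planted_clusters=())
            ds, truth = synthio.simulate_population(cfg)
            q = truth.strain_subgroup_loadings.to_numpy()
            major = q[:, 0] > 0.5
            if major.all() or not major.any():
                pytest.skip("degenerate subgroup split")
            f1 = ds.snp.to_numpy()[major].mean(axis=0)
            f2 = ds.snp.to_numpy()[~major].mean(axis=0)
            return float(np.abs(f1 - f2).mean())

        assert mean_abs_diff(0.02) < mean_abs_diff(0.30)


class TestSimulatePhenotypes:
    def test_null_phenotype_is_gaussian_noise(self):
        cfg = _single_cluster_config(
            phenotype_effect=0.0, structure_effect=0.0, seed=21,
            n_serpentine=100, n_nonserpentine=100,
        )
        ds, _ = synthio.simulate_population(cfg)
        high = ds.phenotypes["growth_highNi"]
        assert abs(high.mean() - cfg.baseline_high_ni) < 4 * cfg.phenotype_sd / np.sqrt(len(high))
        assert abs(high.std() - cfg.phenotype_sd) < 0.015
        assert stats.normaltest(high).pvalue > 0.001

    def test_vanishing_noise_gives_bimodal_growth(self):
        cfg = _single_cluster_config(phenotype_sd=1e-9, structure_effect=0.0)
        ds, truth = synthio.simulate_population(cfg)
        merged = ds.phenotypes.set_index("strain")
        carriers = set(truth.cluster_carriers["clusterA"])
        for strain, row in merged.iterrows():
            expected = cfg.baseline_high_ni + (
                cfg.phenotype_effect if strain in carriers else 0.0
            )
            assert row["growth_highNi"] == pytest.approx(expected, abs=1e-6)

    def test_low_ni_growth_has_no_causal_term(self):
        cfg = _single_cluster_config(phenotype_sd=1e-9, structure_effect=0.0)
        ds, truth = synthio.simulate_population(cfg)
        low = ds.phenotypes.set_index("strain")["growth_lowNi"]
        assert low.std() < 1e-6  # all strains equal: no carrier signal


class TestFragmentGenomes:
    def test_huge_contig_size_gives_single_contig_per_strain(self):
        cfg = _single_cluster_config(contig_mean_genes=100_000)
        ds, _ = synthio.simulate_population(cfg)
        per_strain = ds.layouts.groupby("strain")["contig"].nunique()
        assert (per_strain == 1).all()

    def test_cluster_genes_packed_within_span_on_one_contig(self, small_dataset):
        ds, truth = small_dataset
        spec_by_cluster = dict(
            zip(truth.cluster_genes, ds.config.planted_clusters)
        )
        for cid, genes in truth.cluster_genes.items():
            sub = ds.layouts[ds.layouts["group_id"].isin(genes)]
            for strain, grp in sub.groupby("strain"):
                assert grp["contig"].nunique() == 1
                span = grp["end"].max() - grp["start"].min() + 1
                assert span <= spec_by_cluster[cid].span_bp

    def test_coordinates_are_one_based_and_non_overlapping(self, small_dataset):
        ds, _ = small_dataset
        assert (ds.layouts["start"] >= 1).all()
        for _, grp in ds.layouts.groupby(["strain", "contig"]):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()


class TestHomologDistances:
    def test_zero_shift_gives_identical_distributions(self):
        cfg = _single_cluster_config(homolog_shift=0.0, accessory_pool=1000, seed=31)
        ds, truth = synthio.simulate_population(cfg)
        tab = ds.homolog_distances
        cand = tab.loc[tab["candidate_flag"], "distance_16S"]
        rest = tab.loc[~tab["candidate_flag"], "distance_16S"]
        assert stats.ks_2samp(cand, rest).pvalue > 0.01

    def test_all_candidates_is_degenerate(self, small_dataset):
        ds, _ = small_dataset
        acc = [c for c in ds.presence.columns if not c.startswith("core")]
        with pytest.raises(ValueError, match="reference distribution"):
            synthio.simulate_homolog_distances(ds.presence[acc], acc, ds.config)


class TestAccessoryIdentification:
    def test_no_dropout_no_misclassification(self, small_dataset):
        ds, _ = small_dataset
        report = synthio.simulate_accessory_identification(
            ds.presence, dropout_rate=0.0, n_reps=3, seed=1
        )
        assert report.core_to_accessory_rate == 0.0
        assert report.accessory_freq_distortion == 0.0

    def test_total_dropout_raises_degenerate_partition(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="pan-genome is empty"):
            synthio.simulate_accessory_identification(
                ds.presence, dropout_rate=1.0, n_reps=1, seed=1
            )

    def test_rate_validation(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            synthio.simulate_accessory_identification(ds.presence, -0.1, 1, 1)
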