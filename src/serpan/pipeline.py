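"""End-to-end orchestration: simulate or ingest, then associate, cluster,
test the HGT shift, and partition variance, with one config and one report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, biogeo, clusters, hgt, io, pangenome, synthio


@dataclass
class RunConfig:
    """Single configuration for a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str = "serpan_run"
    seed: int = 0
    fdr_level: float = 0.10
    bonferroni_alpha: float = 0.05
    low_ni_fdr_level: float = 0.20
    min_minor: int = 2
    min_tandem: int = 4
    gap_bp: int = 10_000
    min_jaccard: float = 0.5
    n_perm: int = 999
    n_boot: int = 200
    fdr_method: str = "bh"
    paths: dict[str, str] = field(default_factory=dict)  # file mode inputs
    sim: dict[str, Any] = field(default_factory=dict)  # SimConfig overrides

    REQUIRED_FILES = (
        "presence_absence",
        "snp_matrix",
        "phenotypes",
        "q_matrix",
        "gff3_dir",
        "homolog_distances",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode: {self.mode}")
        for level in (self.fdr_level, self.low_ni_fdr_level, self.bonferroni_alpha):
            if not 0 < level < 1:
                raise ValueError("significance levels must lie in (0, 1)")
        if self.mode == "files":
            missing = [k for k in self.REQUIRED_FILES if k not in self.paths]
            if missing:
                raise ValueError(f"file mode requires input paths: {missing}")
            absent = [k for k in self.REQUIRED_FILES if not Path(self.paths[k]).exists()]
            if absent:
                raise ValueError(
                    "missing input files: "
                    + ", ".join(f"{k}={self.paths[k]}" for k in absent)
                )


@dataclass
class RunReport:
    summary: dict[str, Any]
    gene_results: pd.DataFrame
    snp_results: pd.DataFrame
    cluster_table: pd.DataFrame
    hgt_table: pd.DataFrame
    permanova_core: pd.DataFrame
    permanova_accessory: pd.DataFrame
    out_dir: str


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        sim_kwargs = dict(config.sim)
        specs = sim_kwargs.pop("planted_clusters", None)
        if specs is not None:
            sim_kwargs["planted_clusters"] = tuple(
                synthio.ClusterSpec(**s) for s in specs
            )
        sim = synthio.SimConfig(seed=config.seed, **sim_kwargs)
        dataset, truth = synthio.simulate_population(sim)
        return dataset, truth
    p = config.paths
    presence = io.read_matrix_tsv(p["presence_absence"])
    snp = io.read_matrix_tsv(p["snp_matrix"])
    phenotypes = pd.read_csv(p["phenotypes"], sep="\t")
    q = io.read_matrix_tsv(p["q_matrix"])
    homolog = pd.read_csv(p["homolog_distances"], sep="\t")
    layouts = pd.concat(
        [io.read_gff3(f, strain=f.stem) for f in sorted(Path(p["gff3_dir"]).glob("*.gff3"))],
        ignore_index=True,
    )
    strains = phenotypes[["strain", "soil", "reserve"]]
    dataset = synthio.PopulationDataset(
        strains=strains,
        presence=presence,
        group_origin=pd.Series("de-novo", index=presence.columns),
        snp=snp,
        snp_info=pd.DataFrame(columns=["site", "gene_id", "column", "ref", "alt"]),
        phenotypes=phenotypes,
        q_matrix=q,
        layouts=layouts,
        homolog_distances=homolog,
        config=synthio.SimConfig(seed=config.seed),
    )
    return dataset, None


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in dependency order and write a consolidated report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "mode": config.mode}

    try:
        dataset, truth = _load_inputs(config)
        if truth is not None:
            io.write_dataset(dataset, truth, out / "synthetic_inputs")
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc

    strains = dataset.phenotypes.set_index("strain")
    soil = strains["soil"]
    pheno_high = strains["growth_highNi"]
    pheno_low = strains["growth_lowNi"]

    try:
        focal = list(strains.index)
        core_ids, accessory_ids = pangenome.partition_core_accessory(
            dataset.presence, focal
        )
        spectrum = pangenome.gene_frequency_spectrum(dataset.presence)
        summary["n_core"] = len(core_ids)
        summary["n_accessory"] = len(accessory_ids)
        spectrum.to_csv(out / "gene_frequency_spectrum.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError("pangenome", exc) from exc

    try:
        residuals = association.regress_out_structure(
            pheno_high.loc[dataset.q_matrix.index], dataset.q_matrix
        )
        gene_res, gene_skip = association.gene_content_association(
            dataset.presence.loc[residuals.index, accessory_ids],
            residuals,
            soil_labels=soil,
            raw_phenotype=pheno_high,
            min_minor=config.min_minor,
        )
        gene_res = association.annotate_significance(
            gene_res, fdr_method=config.fdr_method, bonferroni_alpha=config.bonferroni_alpha
        )
        snp_res, snp_skip = association.snp_association(
            dataset.snp.loc[residuals.index],
            residuals,
            soil_labels=soil,
            raw_phenotype=pheno_high,
            min_minor=config.min_minor,
        )
        snp_res = association.annotate_significance(
            snp_res, fdr_method=config.fdr_method, bonferroni_alpha=config.bonferroni_alpha
        )
        gene_hits = association.significant_set(gene_res, config.fdr_level)
        snp_hits = association.significant_set(snp_res, config.fdr_level)

        residuals_low = association.regress_out_structure(
            pheno_low.loc[dataset.q_matrix.index], dataset.q_matrix
        )
        low_res, _ = association.gene_content_association(
            dataset.presence.loc[residuals.index, accessory_ids],
            residuals_low,
            min_minor=config.min_minor,
        )
        low_res = association.annotate_significance(low_res, fdr_method=config.fdr_method)
        low_hits = association.significant_set(low_res, config.low_ni_fdr_level)

        summary["n_gene_candidates_fdr"] = int(len(gene_hits))
        summary["n_gene_candidates_bonferroni"] = int(gene_res["bonferroni_sig"].sum())
        summary["n_snp_candidates_fdr"] = int(len(snp_hits))
        summary["n_snp_candidates_bonferroni"] = int(snp_res["bonferroni_sig"].sum())
        summary["n_lowNi_gene_candidates"] = int(len(low_hits))
        for df, name in [
            (gene_res, "gene_associations.tsv"),
            (snp_res, "snp_associations.tsv"),
            (gene_skip, "gene_skipped.tsv"),
            (snp_skip, "snp_skipped.tsv"),
        ]:
            df.to_csv(out / name, sep="\t", index=False)
        _write_table1(gene_hits, snp_hits, out / "candidate_table.tsv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("association", exc) from exc

    try:
        candidate_ids = set(gene_hits["variant_id"])
        called = clusters.call_clusters(
            dataset.layouts, candidate_ids, config.min_tandem, config.gap_bp
        )
        families = clusters.match_clusters_across_strains(called, config.min_jaccard)
        cluster_table = clusters.cluster_summary(
            families, gene_res, dataset.presence, soil
        )
        cluster_table.to_csv(out / "cluster_families.tsv", sep="\t", index=False)
        _write_cluster_bed(called, out / "cluster_spans.bed")
        summary["n_clusters"] = len(called)
        summary["n_cluster_families"] = len(families)
        summary["n_families_ge10_candidates"] = int(
            (cluster_table["n_candidates"] >= 10).sum()
        )
        summary["n_perfectly_assorting_genes"] = (
            int(cluster_table["n_perfectly_assorting"].max())
            if len(cluster_table)
            else 0
        )
        summary["largest_family_span_bp"] = (
            int(cluster_table["max_span_bp"].max()) if len(cluster_table) else 0
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("clusters", exc) from exc

    try:
        homolog = dataset.homolog_distances.copy()
        # recompute candidate flags/tiers from this run's association results
        qmap = gene_res.set_index("variant_id")["q"]
        homolog["q"] = homolog["group_id"].map(qmap)
        homolog["candidate_flag"] = homolog["q"] < config.fdr_level
        tier = np.full(len(homolog), -1)
        for t in (10, 5, 1):
            tier[homolog["q"].to_numpy() < t / 100] = t
        homolog["fdr_tier"] = tier
        if homolog["candidate_flag"].sum() >= 2:
            hgt_table = hgt.distance_shift_test(homolog)
            summary["hgt_mean_shift"] = float(
                hgt_table.loc[hgt_table["tier"] == "all", "mean_shift"].iloc[0]
            )
        else:
            hgt_table = pd.DataFrame()
            summary["hgt_mean_shift"] = None
        hgt_table.to_csv(out / "hgt_shift.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("hgt", exc) from exc

    try:
        factors = strains[["soil", "reserve"]]
        d_core = biogeo.snp_distance(dataset.snp.loc[strains.index])
        d_acc = biogeo.gene_content_distance(
            dataset.presence.loc[strains.index, accessory_ids]
        )
        perm_core = biogeo.permanova(
            d_core, factors, n_perm=config.n_perm, seed=config.seed
        )
        perm_acc = biogeo.permanova(
            d_acc, factors, n_perm=config.n_perm, seed=config.seed
        )
        perm_core.to_csv(out / "permanova_core.tsv", sep="\t")
        perm_acc.to_csv(out / "permanova_accessory.tsv", sep="\t")
        io.write_nexus_distance(d_core, out / "core_distances.nex")
        io.write_nexus_distance(d_acc, out / "accessory_distances.nex")
        summary["permanova"] = {
            "core_soil_R2": float(perm_core.loc["soil", "R2"]),
            "core_reserve_R2": float(perm_core.loc["reserve", "R2"]),
            "accessory_soil_R2": float(perm_acc.loc["soil", "R2"]),
            "accessory_reserve_R2": float(perm_acc.loc["reserve", "R2"]),
        }
        if config.n_boot > 0:
            boot = biogeo.bootstrap_r2_ci(
                d_acc, factors, n_boot=config.n_boot, seed=config.seed
            )
            boot.to_csv(out / "bootstrap_r2_accessory.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError("biogeo", exc) from exc

    manifest = {
        "serpan_version": __version__,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("paths",)
        },
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    report = RunReport(
        summary=summary,
        gene_results=gene_res,
        snp_results=snp_res,
        cluster_table=cluster_table,
        hgt_table=hgt_table,
        permanova_core=perm_core,
        permanova_accessory=perm_acc,
        out_dir=str(out),
    )
    (out / "report.md").write_text(make_report(report))
    return report


def _write_table1(gene_hits: pd.DataFrame, snp_hits: pd.DataFrame, path: Path) -> None:
    cols = ["variant_id", "variant_kind", "q", "effect", "freq_S", "freq_N"]
    table = pd.concat([gene_hits, snp_hits], ignore_index=True)
    if table.empty:
        table = pd.DataFrame(columns=cols)
    out = table[cols].copy()
    out["freq_S"] = pd.to_numeric(out["freq_S"]).round(2)
    out["freq_N"] = pd.to_numeric(out["freq_N"]).round(2)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_cluster_bed(called, path: Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(called, key=lambda c: (c.strain, c.contig, c.start)):
            fh.write(
                f"{c.contig}\t{c.start - 1}\t{c.end}\t"
                f"{c.strain}_n{c.n_candidates}\n"
            )


def make_report(report: RunReport) -> str:
    """Deterministic human-readable markdown summary of one run."""
    s = report.summary
    lines = [
        "# serpan run report",
        "",
        f"- mode: {s.get('mode')}  seed: {s.get('seed')}",
        f"- core genes: {s.get('n_core')}  accessory genes: {s.get('n_accessory')}",
        "",
        "## Association (high-Ni growth)",
        f"- accessory gene candidates at FDR: {s.get('n_gene_candidates_fdr', 0)}"
        f" (Bonferroni: {s.get('n_gene_candidates_bonferroni', 0)})",
        f"- SNP candidates at FDR: {s.get('n_snp_candidates_fdr', 0)}"
        f" (Bonferroni: {s.get('n_snp_candidates_bonferroni', 0)})",
        f"- low-Ni gene candidates (no-hit contract): {s.get('n_lowNi_gene_candidates', 0)}",
        "",
        "## Candidate clusters",
        f"- clusters called: {s.get('n_clusters', 0)}"
        f" in {s.get('n_cluster_families', 0)} families",
        f"- families with >= 10 candidates: {s.get('n_families_ge10_candidates', 0)}",
        f"- perfectly assorting genes in best family: "
        f"{s.get('n_perfectly_assorting_genes', 0)}",
        f"- largest family span (bp): {s.get('largest_family_span_bp', 0)}",
        "",
        "## Horizontal transfer",
        f"- candidate-minus-noncandidate mean 16S shift: {s.get('hgt_mean_shift')}",
        "",
        "## Variance partitioning (PERMANOVA R²)",
    ]
    perm = s.get("permanova", {})
    for key in sorted(perm):
        lines.append(f"- {key}: {perm[key]:.4f}")
    lines.append("")
    return "\n".join(lines)
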