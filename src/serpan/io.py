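"""Readers and writers for the pipeline's tabular and sequence formats.

Everything is plain text: TSV matrices and tables, per-strain GFF3 layouts,
aligned FASTA per core gene, a minimal VCF-like SNP export (CHROM = gene id,
POS = alignment column), a NEXUS distance-matrix export for external network
tools, and a JSON ground-truth dump for synthetic runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .synthio import PopulationDataset, SyntheticTruth, core_alignments

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="strain")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="strain")


def write_gff3(layout: pd.DataFrame, path: str | Path) -> None:
    """Write one strain's contig layout as GFF3 (1-based inclusive, + strand)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in layout.sort_values(["contig", "start"]).iterrows():
            fh.write(
                f"{row['contig']}\tserpan\tgene\t{row['start']}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\tID={row['group_id']}\n"
            )


def read_gff3(path: str | Path, strain: str | None = None) -> pd.DataFrame:
    """Read a GFF3 gene layout back into contig-map columns."""
    rows = []
    strain = strain if strain is not None else Path(path).stem
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                (
                    strain,
                    parts[0],
                    attrs.get("ID", parts[8]),
                    int(parts[3]),
                    int(parts[4]),
                    parts[6],
                )
            )
    df = pd.DataFrame(
        rows, columns=["strain", "contig", "group_id", "start", "end", "strand"]
    )
    return df.sort_values(["strain", "contig", "start"], kind="stable").reset_index(
        drop=True
    )


def write_fasta_alignment(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_vcf_like(snp_matrix: pd.DataFrame, snp_info: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF-like export: CHROM = gene id, POS = alignment column."""
    strains = list(snp_matrix.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=serpan\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(strains) + "\n")
        for _, row in snp_info.iterrows():
            ref = row.get("ref", "A")
            alt = row.get("alt", "G")
            calls = "\t".join(str(int(v)) for v in snp_matrix[row["site"]])
            fh.write(
                f"{row['gene_id']}\t{row['column']}\t{row['site']}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_nexus_distance(distance: pd.DataFrame, path: str | Path) -> None:
    """NEXUS distances block (for NeighborNet/SplitsTree-style tools)."""
    taxa = list(distance.index)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(taxa)};\n  TAXLABELS\n")
        for t in taxa:
            fh.write(f"    {t}\n")
        fh.write("  ;\nEND;\nBEGIN DISTANCES;\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for t in taxa:
            vals = " ".join(f"{distance.loc[t, u]:.6f}" for u in taxa)
            fh.write(f"    {t} {vals}\n")
        fh.write("  ;\nEND;\n")


def write_dataset(dataset: PopulationDataset, truth: SyntheticTruth, out_dir: str | Path) -> dict:
    """Write every table of a synthetic dataset; returns a path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    write_matrix_tsv(dataset.presence, _p("presence_absence.tsv"))
    write_matrix_tsv(dataset.snp, _p("snp_matrix.tsv"))
    dataset.snp_info.to_csv(_p("snp_sites.tsv"), sep="\t", index=False)
    dataset.phenotypes.to_csv(_p("phenotypes.tsv"), sep="\t", index=False)
    write_matrix_tsv(dataset.q_matrix, _p("q_matrix.tsv"))
    dataset.homolog_distances.to_csv(_p("homolog_distances.tsv"), sep="\t", index=False)
    dataset.strains.to_csv(_p("strains.tsv"), sep="\t", index=False)
    write_vcf_like(dataset.snp, dataset.snp_info, _p("snps.vcf"))

    gff_dir = out / "gff3"
    gff_dir.mkdir(exist_ok=True)
    for strain, layout in dataset.layouts.groupby("strain"):
        write_gff3(layout, gff_dir / f"{strain}.gff3")
    paths["gff3_dir"] = str(gff_dir)

    aln_dir = out / "core_alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene_id, seqs in core_alignments(dataset):
        write_fasta_alignment(seqs, aln_dir / f"{gene_id}.fasta")
    paths["core_alignments_dir"] = str(aln_dir)

    truth_json = {
        "causal_gene_ids": sorted(truth.causal_gene_ids),
        "true_effects": truth.true_effects,
        "cluster_genes": truth.cluster_genes,
        "cluster_carriers": truth.cluster_carriers,
        "strain_subgroup_loadings": truth.strain_subgroup_loadings.round(9)
        .reset_index()
        .rename(columns={"index": "strain"})
        .to_dict(orient="records"),
        "planted_cluster_coords": {
            cid: {s: list(c) for s, c in coords.items()}
            for cid, coords in truth.planted_cluster_coords.items()
        },
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return paths
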