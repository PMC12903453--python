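"""Readers and writers for the standard formats the pipeline touches.

VCF reading goes through cyvcf2; the writer emits plain-text VCF v4.2 (GT
field only, ``./.`` for missing, contig lines in the header), which is all a
dosage matrix needs. Gene models are written as GFF3 ``gene`` features
(1-based inclusive). Everything tabular is TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    GenotypeMatrix,
    GroundTruth,
    validate_annotation,
    validate_phenotypes,
)

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    path = Path(path)
    contigs = dict.fromkeys(geno.sites["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in contigs:
            if chrom_lengths and chrom in chrom_lengths:
                fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.accession_ids) + "\n")
        sites = geno.sites
        for j in range(geno.n_sites):
            gts = "\t".join(
                _GT.get(geno.dosage[i, j], "./.") for i in range(geno.n_accessions))
            fh.write(f"{sites['chrom'].iat[j]}\t{sites['pos'].iat[j]}\t"
                     f"{sites['chrom'].iat[j]}_{sites['pos'].iat[j]}\t"
                     f"{sites['ref'].iat[j]}\t{sites['alt'].iat[j]}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, cultivar_types: dict[str, str] | None = None,
             default_type: str = "TC") -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into dosage form.

    ``cultivar_types`` maps accession id to germplasm class; unlisted
    accessions get ``default_type``.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic sites only
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
    vcf.close()
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    types = [(cultivar_types or {}).get(s, default_type) for s in samples]
    return GenotypeMatrix(samples, types, sites, dosage)


def write_groups_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"accession": geno.accession_ids,
                  "type": geno.cultivar_type}).to_csv(path, sep="\t", index=False)


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"].astype(str), df["type"].astype(str)))


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(pheno).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as GFF3 ``gene`` features (1-based inclusive)."""
    validate_annotation(genes)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\trootability\tgene\t{row.start}\t{row.end}\t.\t"
                     f"{row.strand}\t.\tID={row.gene_id}\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read ``gene`` features from a GFF3 file into an annotation table."""
    names = ["chrom", "source", "feature", "start", "end", "score", "strand",
             "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype={"chrom": str})
    df = df[df["feature"] == "gene"].copy()
    df["gene_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    out = df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)
    return validate_annotation(out)


def write_counts_tsv(counts: np.ndarray, gene_ids: list[str], sample_ids: list[str],
                     path: str | Path) -> None:
    pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                 columns=sample_ids).to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    obj = {
        "sweep_intervals": [list(t) for t in truth.sweep_intervals],
        "causal_snps": [[i, eff] for i, eff in truth.causal_snps],
        "true_modules": truth.true_modules,
        "target_h2": truth.target_h2,
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_truth_json(path: str | Path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    return GroundTruth(
        sweep_intervals=[tuple(t) for t in obj.get("sweep_intervals", [])],
        causal_snps=[(int(i), dict(e)) for i, e in obj.get("causal_snps", [])],
        true_modules=dict(obj.get("true_modules", {})),
        target_h2=dict(obj.get("target_h2", {})),
    )


def intervals_to_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write merged intervals as BED (0-based half-open)."""
    bed = pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"].astype(int) - 1,
        "end": intervals["end"].astype(int),
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
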