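"""Core in-memory containers shared across the pipeline.

Array-heavy objects (genotypes, expression) are small dataclasses wrapping
numpy arrays; purely tabular results (phenotypes, window statistics, gene
annotations, association results) travel as pandas DataFrames with documented
column contracts — see the functions that produce them.

Genotypes are diploid allele dosages in {0, 1, 2} with NaN for missing calls.
Chrysanthemum itself is polyploid; the panel this models represents GBS calls
as diploid dosages, and that simplification is kept throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Germplasm classes: spray cut, traditional, potted-and-groundcover, wild.
CULTIVAR_TYPES = ("SCC", "TC", "PGC", "WC")

#: The eleven rooting traits, in canonical column order.
TRAITS = ("TL", "PA", "SA", "AD", "V", "NT", "UFW", "NR", "AL", "UDW", "MTL")

#: Phenotype table columns preceding the trait block.
PHENO_ID_COLS = ("accession", "type", "year", "rep")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of accessions.

    Attributes
    ----------
    accession_ids : list of str
        Unique accession identifiers, one per matrix row.
    cultivar_type : list of str
        Per-accession germplasm class, each in :data:`CULTIVAR_TYPES`.
    sites : DataFrame
        One row per SNP with columns ``chrom`` (str), ``pos`` (1-based int),
        ``ref``, ``alt`` (single characters). Positions strictly increase
        within each chromosome.
    dosage : ndarray, shape (n_accessions, n_sites)
        Alternate-allele dosage in {0, 1, 2}; ``nan`` marks a missing call.
    """

    accession_ids: list[str]
    cultivar_type: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(self.accession_ids) != len(set(self.accession_ids)):
            raise ValueError("accession_ids must be unique")
        if len(self.cultivar_type) != len(self.accession_ids):
            raise ValueError("cultivar_type length must match accession count")
        bad = set(self.cultivar_type) - set(CULTIVAR_TYPES)
        if bad:
            raise ValueError(f"unknown cultivar types: {sorted(bad)}")
        if self.dosage.shape != (len(self.accession_ids), len(self.sites)):
            raise ValueError("dosage shape does not match accessions x sites")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or missing")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must strictly increase within a chromosome")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def snp_ids(self) -> list[str]:
        """Identifiers of the form ``Chr1_12345`` used in association output."""
        return [f"{c}_{p}" for c, p in zip(self.sites["chrom"], self.sites["pos"])]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            cultivar_type=list(self.cultivar_type),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
        )

    def type_mask(self, cultivar: str) -> np.ndarray:
        return np.array([t == cultivar for t in self.cultivar_type])


@dataclass
class ExpressionMatrix:
    """Raw RNA-seq counts with gene lengths and sample metadata.

    ``trait_values`` optionally carries per-sample values of the key rooting
    traits (TL, SA, AD, NR) for module–trait correlation.
    """

    gene_ids: list[str]
    gene_length_bp: np.ndarray
    counts: np.ndarray  # genes x samples, non-negative integers
    sample_ids: list[str]
    sample_group: list[str]  # per sample, in {"strong", "weak"}
    trait_values: pd.DataFrame | None = None  # samples x traits

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_length_bp = np.asarray(self.gene_length_bp, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match genes x samples")
        if (self.counts < 0).any() or not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        if (self.gene_length_bp <= 0).any():
            raise ValueError("gene lengths must be positive")
        if len(self.sample_group) != len(self.sample_ids):
            raise ValueError("sample_group must label every sample")
        bad = set(self.sample_group) - {"strong", "weak"}
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GroundTruth:
    """Record of what a synthetic dataset planted, for recovery checks."""

    sweep_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    causal_snps: list[tuple[int, dict[str, float]]] = field(default_factory=list)
    true_modules: dict[str, str] = field(default_factory=dict)
    target_h2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, h2 in self.target_h2.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"target_h2[{trait}] outside [0, 1]")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table's invariants and return it.

    Expected columns: ``accession, type, year, rep`` then the trait block.
    Trait values are >= 0 or NaN; wherever TL and NR are both present with
    NR > 0, AL equals TL/NR (the average-root-length identity).
    """
    missing = [c for c in (*PHENO_ID_COLS, *TRAITS) if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    vals = pheno.loc[:, list(TRAITS)]
    if (vals < 0).any().any():
        raise ValueError("trait values must be >= 0 or missing")
    ok = pheno["TL"].notna() & pheno["NR"].notna() & (pheno["NR"] > 0) & pheno["AL"].notna()
    if ok.any():
        expect = pheno.loc[ok, "TL"] / pheno.loc[ok, "NR"]
        rel = np.abs(pheno.loc[ok, "AL"] - expect) / np.maximum(np.abs(expect), 1e-300)
        if (rel > 1e-6).any():
            raise ValueError("AL must equal TL/NR where both are present")
    return pheno


def validate_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-annotation table (gene_id, chrom, start, end, strand)."""
    need = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in need if c not in genes.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("gene_ids must be unique")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must be <= end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return genes
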