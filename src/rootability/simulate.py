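"""Synthetic panel generator.

Emulates the structure of a diverse chrysanthemum cutting panel so that every
downstream stage (composite scoring, sweep scan, GWAS, co-expression) can be
exercised and validated against planted truth at desk scale:

* genotypes — 188 accessions in 3 subpopulations whose allele frequencies
  diverge under a Balding–Nichols model, with optional planted sweep regions
  where the "improved" germplasm class has shifted frequencies and reduced
  diversity;
* phenotypes — the 11 rooting traits, replicated over years and blocks, with
  per-trait broad-sense heritability targets and a 3-latent-factor trait
  correlation structure (length/area, diameter, number);
* expression — overdispersed counts with planted co-expression modules driven
  by latent factors, planted fold changes between strong and weak rooters, and
  module-linked sample traits.

Every generator is a pure function of its configuration and seed: per-stage
child seeds are derived from the master seed with numpy's SeedSequence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    TRAITS,
    ExpressionMatrix,
    GenotypeMatrix,
    GroundTruth,
    validate_phenotypes,
)

# Trait scales used to place simulated values on a realistic measurement
# scale (per-trait mean and SD of a rooting assay panel, two-year averages).
TRAIT_MEANS = {
    "TL": 38.1, "PA": 2.6, "SA": 8.1, "AD": 0.72, "V": 0.145, "NT": 41.9,
    "UFW": 0.26, "NR": 16.8, "AL": 2.7, "UDW": 0.03, "MTL": 50.6,
}
TRAIT_SDS = {
    "TL": 20.1, "PA": 1.4, "SA": 4.2, "AD": 0.16, "V": 0.085, "NT": 23.1,
    "UFW": 0.12, "NR": 8.7, "AL": 1.7, "UDW": 0.015, "MTL": 21.4,
}

# Default per-trait broad-sense heritability targets for the panel.
DEFAULT_H2 = {
    "TL": 0.62, "PA": 0.64, "SA": 0.64, "AD": 0.55, "V": 0.68, "NT": 0.55,
    "UFW": 0.58, "NR": 0.55, "AL": 0.52, "UDW": 0.37, "MTL": 0.60,
}

# Loadings of the 11 traits on 3 genetic latent factors: length/area,
# diameter, and root number. AD loads negatively on factor 1, echoing its
# negative correlation with the length traits.
_FACTOR_LOADINGS = {
    "TL": (0.90, 0.00, 0.25), "PA": (0.90, 0.05, 0.15), "SA": (0.90, 0.15, 0.15),
    "AD": (-0.35, 0.85, 0.00), "V": (0.85, 0.30, 0.10), "NT": (0.60, -0.10, 0.55),
    "UFW": (0.80, 0.20, 0.15), "NR": (0.30, 0.00, 0.90), "AL": (0.60, 0.00, -0.55),
    "UDW": (0.70, 0.20, 0.10), "MTL": (0.88, 0.00, 0.10),
}

_SUBPOP_TYPES = ("SCC", "TC", "PGC")  # subpopulation -> dominant germplasm class


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def _sweep_frequency(q: np.ndarray, delta_p: float, diversity_fold: float) -> np.ndarray:
    """Push allele frequencies toward fixation inside a sweep.

    First shifts each frequency by ``delta_p`` toward its nearer boundary,
    then rescales so expected heterozygosity 2q(1-q) drops by
    ``diversity_fold`` relative to the pre-shift value, staying on the same
    side of 0.5.
    """
    q = np.asarray(q, dtype=float)
    h_target = 2.0 * q * (1.0 - q) / max(diversity_fold, 1.0)
    toward_one = q >= 0.5
    shifted = np.where(toward_one, q + delta_p, q - delta_p)
    shifted = np.clip(shifted, 0.0, 1.0)
    # heterozygosity cap: solve 2x(1-x) = h on the chosen side of 0.5
    disc = np.sqrt(np.maximum(0.25 - h_target / 2.0, 0.0))
    lo, hi = 0.5 - disc, 0.5 + disc
    out = np.where(toward_one, np.maximum(shifted, hi), np.minimum(shifted, lo))
    return np.clip(out, 0.0, 1.0)


def simulate_genotypes(
    n_accessions: int = 188,
    subpop_sizes: tuple[int, ...] = (70, 59, 59),
    chrom_lengths: dict[str, int] | None = None,
    snp_density: float = 2000 / 1_000_000,
    base_fst: float = 0.05,
    sweep_spec: list[dict] | None = None,
    missing_rate: float = 0.02,
    family_size: int = 0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Simulate a structured SNP panel with optional planted sweeps.

    Parameters
    ----------
    subpop_sizes
        Accessions per subpopulation; subpopulations are labelled with the
        germplasm classes SCC, TC, PGC in order (extra subpopulations beyond
        three are labelled WC).
    snp_density
        Expected SNPs per bp (default 2 000 per Mb).
    base_fst
        Balding–Nichols divergence level of subpopulation allele frequencies
        from the shared ancestral frequency.
    sweep_spec
        Each entry: ``{"chrom", "start", "end", "improved", "delta_p",
        "diversity_fold"}``. Inside the interval, the improved germplasm
        class's allele frequencies are shifted by ``delta_p`` toward fixation
        and its expected heterozygosity reduced ``diversity_fold``-fold.
    family_size
        If > 0, accessions within each subpopulation are organized into
        full-sib families of this size (two founders per family, the rest
        Mendelian offspring), adding within-group relatedness beyond what
        ancestry components capture — as in real germplasm panels. 0 keeps
        all accessions unrelated.
    """
    if sum(subpop_sizes) != n_accessions:
        raise ValueError("subpop_sizes must sum to n_accessions")
    if not 0.0 <= base_fst < 1.0:
        raise ValueError("base_fst must be in [0, 1)")
    if snp_density <= 0:
        raise ValueError("snp_density must be positive")
    if chrom_lengths is None:
        chrom_lengths = {"Chr1": 1_000_000, "Chr2": 1_000_000, "Chr3": 1_000_000}
    sweep_spec = list(sweep_spec or [])
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sw in sweep_spec:
        c, s, e = sw["chrom"], int(sw["start"]), int(sw["end"])
        if c not in chrom_lengths or s < 1 or e > chrom_lengths[c] or s > e:
            raise ValueError(f"sweep interval {c}:{s}-{e} outside chromosome bounds")
        for s0, e0 in by_chrom.get(c, []):
            if s <= e0 and e >= s0:
                raise ValueError(f"overlapping sweep intervals on {c}")
        by_chrom.setdefault(c, []).append((s, e))

    rng_sites, rng_freq, rng_dos, rng_miss = _child_rngs(seed, 4)
    n_pops = len(subpop_sizes)
    types = [(_SUBPOP_TYPES[i] if i < len(_SUBPOP_TYPES) else "WC") for i in range(n_pops)]
    cultivar = [t for t, n in zip(types, subpop_sizes) for _ in range(n)]
    accession_ids = [f"acc{i + 1:03d}" for i in range(n_accessions)]

    chroms, positions = [], []
    for chrom in chrom_lengths:  # insertion order is the genome order
        length = chrom_lengths[chrom]
        n_snp = rng_sites.poisson(snp_density * length)
        pos = np.sort(rng_sites.choice(np.arange(1, length + 1), size=min(n_snp, length),
                                       replace=False))
        chroms.extend([chrom] * len(pos))
        positions.extend(pos.tolist())
    m = len(positions)
    alleles = np.array(list("ACGT"))
    ref = rng_sites.choice(alleles, size=m)
    alt_offset = rng_sites.integers(1, 4, size=m)
    alt = alleles[(np.searchsorted(alleles, ref) + alt_offset) % 4]
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": ref, "alt": alt})

    p_anc = rng_freq.uniform(0.05, 0.95, size=m)
    freqs = np.empty((n_pops, m))
    if base_fst > 0:
        a = p_anc * (1.0 - base_fst) / base_fst
        b = (1.0 - p_anc) * (1.0 - base_fst) / base_fst
        for k in range(n_pops):
            freqs[k] = rng_freq.beta(a, b)
    else:
        freqs[:] = p_anc

    for sw in sweep_spec:
        imp = sw.get("improved", "SCC")
        try:
            k = types.index(imp)
        except ValueError:
            raise ValueError(f"improved class {imp!r} not among subpopulations") from None
        in_sweep = ((sites["chrom"] == sw["chrom"])
                    & (sites["pos"] >= sw["start"]) & (sites["pos"] <= sw["end"])).to_numpy()
        freqs[k, in_sweep] = _sweep_frequency(
            freqs[k, in_sweep], float(sw.get("delta_p", 0.6)),
            float(sw.get("diversity_fold", 5.0)))

    dosage = np.empty((n_accessions, m))
    row = 0
    for k, n in enumerate(subpop_sizes):
        block = rng_dos.binomial(2, freqs[k], size=(n, m)).astype(float)
        if family_size > 1:
            # full-sib families: rows 0,1 of each family are founders, the
            # rest draw one allele from each founder per site (Mendelian)
            for f0 in range(0, n, family_size):
                f1 = min(f0 + family_size, n)
                if f1 - f0 < 3:
                    continue
                p1, p2 = block[f0], block[f0 + 1]
                kids = f1 - f0 - 2
                a1 = rng_dos.random((kids, m)) < p1 / 2.0
                a2 = rng_dos.random((kids, m)) < p2 / 2.0
                block[f0 + 2:f1] = a1.astype(float) + a2.astype(float)
        dosage[row:row + n] = block
        row += n
    if missing_rate > 0:
        mask = rng_miss.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    geno = GenotypeMatrix(accession_ids, cultivar, sites, dosage)
    truth = GroundTruth(
        sweep_intervals=[(sw["chrom"], int(sw["start"]), int(sw["end"])) for sw in sweep_spec])
    return geno, truth


def default_sweep_spec(chrom_lengths: dict[str, int] | None = None,
                       sweep_bp: int = 100_000,
                       delta_p: float = 0.6,
                       diversity_fold: float = 5.0) -> list[dict]:
    """One centred sweep per chromosome, improved class SCC."""
    if chrom_lengths is None:
        chrom_lengths = {"Chr1": 1_000_000, "Chr2": 1_000_000, "Chr3": 1_000_000}
    spec = []
    for chrom, length in chrom_lengths.items():
        start = (length - sweep_bp) // 2 + 1
        # align to the 10 kb window grid so sweep edges coincide with steps
        start = (start // 10_000) * 10_000 + 1
        spec.append({"chrom": chrom, "start": start, "end": start + sweep_bp - 1,
                     "improved": "SCC", "delta_p": delta_p,
                     "diversity_fold": diversity_fold})
    return spec


def _variance_components_from_spec(spec: dict, l: int, r: int) -> tuple[float, float, float]:
    """Resolve a per-trait variance spec to (Vg, Vge, Ve) on the z-scale."""
    if "Vg" in spec:
        vg, vge, ve = float(spec["Vg"]), float(spec.get("Vge", 0.0)), float(spec.get("Ve", 0.0))
        if min(vg, vge, ve) < 0:
            raise ValueError("variance components must be non-negative")
        return vg, vge, ve
    h2 = float(spec["target_h2"])
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("target_h2 must be in [0, 1]")
    if h2 == 0.0:
        vg, vge, ve = 0.0, 1.0, 1.0
    else:
        vg = 1.0
        s = vg * (1.0 / h2 - 1.0)  # = Vge/l + Ve/(r*l)
        vge = s * l / 2.0
        ve = s * r * l / 2.0
    # normalize so the per-observation z-scale variance is 1: the entry-mean
    # heritability only depends on the ratios, and trait values stay on the
    # stated measurement scale (so the >= 0 floor is rarely binding)
    total = vg + vge + ve
    return vg / total, vge / total, ve / total


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    n_years: int = 2,
    n_reps: int = 3,
    variance_spec: dict[str, dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the replicated multi-year rooting-trait table.

    Each trait value is genetic value (3-factor polygenic structure plus any
    planted causal-SNP effects, empirically scaled to variance Vg) + a year
    main effect + a genotype-by-year deviation (variance Vge) + replicate
    error (variance Ve), mapped onto the trait's measurement scale. AL is then
    recomputed as TL/NR so the derived-trait identity holds exactly.
    """
    if n_years < 1 or n_reps < 1:
        raise ValueError("n_years and n_reps must be >= 1")
    n = genotypes.n_accessions
    variance_spec = variance_spec or {}
    rng_g, rng_y, rng_gy, rng_e = _child_rngs(seed, 4)

    factors = rng_g.standard_normal((n, 3))
    causal = np.zeros((n, len(TRAITS)))
    dos = genotypes.dosage
    for site_idx, effects in truth.causal_snps:
        if not 0 <= site_idx < genotypes.n_sites:
            raise ValueError(f"causal site index {site_idx} out of range")
        x = dos[:, site_idx]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        for t, beta in effects.items():
            causal[:, TRAITS.index(t)] += beta * x

    year_labels = [f"Y{j + 1}" for j in range(n_years)]
    year_shift = rng_y.normal(0.0, 0.4, size=n_years)  # common year main effect (z-scale)

    rows: dict[str, list] = {c: [] for c in ("accession", "type", "year", "rep")}
    data = np.empty((n * n_years * n_reps, len(TRAITS)))
    target_h2: dict[str, float] = {}
    idx = 0
    per_trait = {}
    for ti, trait in enumerate(TRAITS):
        spec = variance_spec.get(trait, {"target_h2": DEFAULT_H2[trait]})
        vg, vge, ve = _variance_components_from_spec(spec, n_years, n_reps)
        target_h2[trait] = vg / (vg + vge / n_years + ve / (n_reps * n_years)) if vg > 0 else 0.0
        load = np.array(_FACTOR_LOADINGS[trait])
        g_raw = factors @ load + causal[:, ti]
        sd = g_raw.std(ddof=0)
        g = g_raw / sd * np.sqrt(vg) if (sd > 0 and vg > 0) else np.zeros(n)
        gy = rng_gy.normal(0.0, np.sqrt(vge), size=(n, n_years)) if vge > 0 else np.zeros((n, n_years))
        per_trait[trait] = (g, gy, ve)

    for i in range(n):
        for j in range(n_years):
            for k in range(n_reps):
                rows["accession"].append(genotypes.accession_ids[i])
                rows["type"].append(genotypes.cultivar_type[i])
                rows["year"].append(year_labels[j])
                rows["rep"].append(k + 1)
                idx += 1
    idx = 0
    err = {t: rng_e.normal(0.0, np.sqrt(per_trait[t][2]), size=(n, n_years, n_reps))
           if per_trait[t][2] > 0 else np.zeros((n, n_years, n_reps)) for t in TRAITS}
    for i in range(n):
        for j in range(n_years):
            for k in range(n_reps):
                for ti, trait in enumerate(TRAITS):
                    g, gy, _ = per_trait[trait]
                    z = g[i] + year_shift[j] + gy[i, j] + err[trait][i, j, k]
                    data[idx, ti] = TRAIT_MEANS[trait] + TRAIT_SDS[trait] * z
                idx += 1

    pheno = pd.DataFrame(rows)
    for ti, trait in enumerate(TRAITS):
        pheno[trait] = np.maximum(data[:, ti], 0.0)
    # count traits are integers; NR >= 1 so the AL = TL/NR identity is defined
    pheno["NT"] = np.round(pheno["NT"])
    pheno["NR"] = np.maximum(np.round(pheno["NR"]), 1.0)
    pheno["AL"] = pheno["TL"] / pheno["NR"]
    truth.target_h2 = target_h2
    return validate_phenotypes(pheno)


def simulate_expression(
    n_genes: int = 1000,
    module_spec: list[dict] | None = None,
    sample_groups: list[str] | None = None,
    trait_links: dict[str, dict] | None = None,
    de_spec: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a counts matrix with planted co-expression modules.

    Parameters
    ----------
    module_spec
        Each entry ``{"name", "size", "loading", "log2fc"?, "factor_cor"?}``.
        Genes of a module share a latent factor; the within-module log-scale
        expression correlation is ``loading**2`` in expectation. ``log2fc``
        plants a strong-vs-weak shift on the whole module. ``factor_cor``
        correlates this module's factor with the previous module's.
    sample_groups
        Per-sample "strong"/"weak" labels; default 15 + 15.
    trait_links
        ``{module_name: {"trait": name, "r": correlation}}`` — generates
        per-sample trait vectors correlated with module factors. Traits not
        linked to any module (of TL, SA, AD, NR) are independent noise.
    de_spec
        Extra per-gene planted log2 fold changes (strong vs weak) keyed by
        gene index, for genes outside any module.
    """
    module_spec = list(module_spec or [])
    if sample_groups is None:
        sample_groups = ["strong"] * 15 + ["weak"] * 15
    trait_links = trait_links or {}
    n_samples = len(sample_groups)
    if sum(m["size"] for m in module_spec) > n_genes:
        raise ValueError("module sizes exceed n_genes")

    rng_f, rng_z, rng_c, rng_t = _child_rngs(seed, 4)
    strong = np.array([g == "strong" for g in sample_groups], dtype=float)

    factors: dict[str, np.ndarray] = {}
    prev = None
    for mod in module_spec:
        f = rng_f.standard_normal(n_samples)
        rho = float(mod.get("factor_cor", 0.0))
        if rho and prev is not None:
            f = rho * factors[prev] + np.sqrt(1 - rho ** 2) * f
        factors[mod["name"]] = f
        prev = mod["name"]

    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    log2_base = rng_z.normal(7.0, 1.2, size=n_genes)
    z = rng_z.standard_normal((n_genes, n_samples))
    # background genes are mostly stably expressed: heterogeneous amplitudes
    # below the module amplitude, so variability filters rank module genes
    # highly, as with real co-regulated programs
    n_module = sum(int(m["size"]) for m in module_spec)
    amplitude = np.ones(n_genes)
    amplitude[n_module:] = rng_z.uniform(0.15, 0.85, size=n_genes - n_module)
    z = z * amplitude[:, None]
    true_modules: dict[str, str] = {}
    shift = np.zeros((n_genes, n_samples))
    row = 0
    for mod in module_spec:
        lam = float(mod["loading"])
        size = int(mod["size"])
        f = factors[mod["name"]]
        # balanced loading signs (activated and repressed halves): the module
        # then has no net library-size footprint, so depth normalization does
        # not erode the planted correlation at desk scale
        sign = np.where(np.arange(size) % 2 == 0, 1.0, -1.0)[:, None]
        z[row:row + size] = sign * lam * f + np.sqrt(1.0 - lam ** 2) * z[row:row + size]
        lfc = float(mod.get("log2fc", 0.0))
        if lfc:
            # regulation direction follows the gene's loading sign, so the
            # strong/weak contrast reinforces (not cancels) the module factor
            shift[row:row + size] = sign * lfc * (strong - 0.5)
        for g in gene_ids[row:row + size]:
            true_modules[g] = mod["name"]
        row += size
    for idx, lfc in (de_spec or {}).items():
        shift[int(idx)] = float(lfc) * (strong - 0.5)

    # amplitude 1.4 on the log2 scale keeps the count-level noise small
    # relative to the latent signal, so within-module correlation stays near
    # its log-scale value loading^2; planted fold changes are added on the
    # exact log2 scale afterwards
    log2_mu = log2_base[:, None] + 1.4 * z + shift
    mu = np.power(2.0, log2_mu)
    # gamma-Poisson with dispersion 0.05 (NB shape 20)
    shape = 20.0
    lam = rng_c.gamma(shape, mu / shape)
    counts = rng_c.poisson(lam)
    gene_length = rng_c.integers(500, 5001, size=n_genes).astype(float)

    trait_cols = {}
    for t in ("TL", "SA", "AD", "NR"):
        linked = [(m, d) for m, d in trait_links.items() if d.get("trait") == t]
        if linked:
            mname, d = linked[0]
            r = float(d.get("r", 0.7))
            zt = r * factors[mname] + np.sqrt(1 - r ** 2) * rng_t.standard_normal(n_samples)
        else:
            zt = rng_t.standard_normal(n_samples)
        trait_cols[t] = TRAIT_MEANS[t] + TRAIT_SDS[t] * zt
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    traits = pd.DataFrame(trait_cols, index=sample_ids)

    expr = ExpressionMatrix(gene_ids, gene_length, counts, sample_ids,
                            list(sample_groups), traits)
    return expr, GroundTruth(true_modules=true_modules)


def filter_snps(genotypes: GenotypeMatrix, maf_min: float = 0.05,
                missing_max: float = 0.20) -> GenotypeMatrix:
    """Retain sites with MAF >= maf_min and missing fraction <= missing_max.

    MAF is computed on non-missing alleles; the filter removes sites strictly
    below the MAF floor or strictly above the missingness ceiling, so boundary
    sites are retained. Site order is preserved; the operation is idempotent.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError("missing_max must be in [0, 1]")
    dos = genotypes.dosage
    present = ~np.isnan(dos)
    n_alleles = 2 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(dos, axis=0) / n_alleles
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf = np.where(n_alleles > 0, maf, 0.0)
    missing_frac = 1.0 - present.mean(axis=0)
    keep = (maf >= maf_min) & (missing_frac <= missing_max)
    if not keep.any():
        warnings.warn("filter_snps removed every site", stacklevel=2)
    return genotypes.take_sites(np.flatnonzero(keep))
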