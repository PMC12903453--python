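"""Association scans for the key rooting traits.

Two scan models are provided, mirroring standard GWAS practice on structured
panels:

* GLM — ordinary least squares of the trait BLUE on population-structure
  covariates (Q) plus the SNP dosage, with a two-sided t-test on the dosage
  coefficient;
* MLM — an EMMAX/P3D mixed model: the polygenic variance ratio
  delta = sigma_e^2 / sigma_g^2 is estimated once by REML on the null model
  over the kinship eigendecomposition, then every SNP is tested by
  generalized least squares under that fixed covariance.

Multiple testing uses a Bonferroni threshold of 1/Me, where Me is the
effective number of independent SNPs. Me may be supplied directly (the
published panel value is 292 493) or estimated with a simplified per-
chromosome eigenvalue rule (Li & Ji 2005 style); the estimator is not the
GEC algorithm used to produce the published value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .datatypes import GenotypeMatrix


@dataclass
class GwasThreshold:
    me: float
    p_threshold: float
    neg_log10: float


def effective_snp_number(geno: GenotypeMatrix) -> float:
    """Per-chromosome eigenvalue-based effective-test counts, summed.

    For each chromosome the eigenvalues lambda of the SNP correlation matrix
    are mapped through f(lambda) = I(lambda >= 1) + (lambda - floor(lambda))
    and summed. Independent SNPs give Me ~= M; perfect LD gives Me ~= 1.
    """
    X = geno.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    total = 0.0
    for _, grp in geno.sites.groupby("chrom", sort=False):
        sub = X[:, grp.index.to_numpy()]
        sd = sub.std(axis=0)
        sub = sub[:, sd > 0]
        if sub.shape[1] == 0:
            continue
        corr = np.corrcoef(sub, rowvar=False)
        lam = np.linalg.eigvalsh(np.atleast_2d(corr))
        lam = np.maximum(lam, 0.0)
        total += float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    m = geno.n_sites
    return float(min(max(total, 1.0), m))


def significance_threshold(me_or_genotypes: float | GenotypeMatrix) -> GwasThreshold:
    """Bonferroni threshold p = 1/Me from a supplied or estimated Me."""
    if isinstance(me_or_genotypes, GenotypeMatrix):
        me = effective_snp_number(me_or_genotypes)
    else:
        me = float(me_or_genotypes)
    if me < 1:
        raise ValueError("Me must be >= 1")
    p = 1.0 / me
    return GwasThreshold(me=me, p_threshold=p, neg_log10=-np.log10(p))


def _impute_dosage(geno: GenotypeMatrix) -> np.ndarray:
    X = geno.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return X


def _scan_frame(geno: GenotypeMatrix, beta, se, p, model: str) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return pd.DataFrame({
        "snp": geno.snp_ids(),
        "chrom": geno.sites["chrom"],
        "pos": geno.sites["pos"],
        "effect": beta,
        "se": se,
        "p": p,
        "neg_log10": neglog,
        "model": model,
    })


def _residual_scan(ystar: np.ndarray, Cstar: np.ndarray, Xstar: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP slope/se/p after projecting covariates out of y and X."""
    n, p_cov = Cstar.shape
    Q, _ = np.linalg.qr(Cstar)
    yr = ystar - Q @ (Q.T @ ystar)
    Xr = Xstar - Q @ (Q.T @ Xstar)
    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    ok = xx > 1e-10 * n
    beta = np.full(Xstar.shape[1], np.nan)
    se = np.full(Xstar.shape[1], np.nan)
    pval = np.full(Xstar.shape[1], np.nan)
    dof = n - p_cov - 1
    yy = float(yr @ yr)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(ok, xy / xx, np.nan)
        rss = np.maximum(yy - b ** 2 * xx, 0.0)
        s2 = rss / dof
        s = np.sqrt(s2 / xx)
        t = b / s
    pv = 2.0 * sps.t.sf(np.abs(t), dof)
    beta[ok] = b[ok]
    se[ok] = s[ok]
    pval[ok] = pv[ok]
    return beta, se, pval


def glm_scan(trait: pd.Series, geno: GenotypeMatrix,
             Q: pd.DataFrame | None = None) -> pd.DataFrame:
    """OLS scan of the trait on [intercept, Q, dosage] per SNP."""
    y, C, X = _align(trait, geno, Q)
    beta, se, p = _residual_scan(y, C, X)
    return _scan_frame(geno, beta, se, p, "GLM")


def _align(trait: pd.Series, geno: GenotypeMatrix, Q: pd.DataFrame | None
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    trait = trait.reindex(geno.accession_ids)
    if trait.isna().any():
        raise ValueError("trait values missing for some accessions")
    y = trait.to_numpy(dtype=float)
    n = len(y)
    C = np.ones((n, 1))
    if Q is not None:
        Qv = Q.reindex(geno.accession_ids).to_numpy(dtype=float)
        if np.isnan(Qv).any():
            raise ValueError("Q rows missing for some accessions")
        C = np.hstack([C, Qv])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("Q columns collinear with intercept")
    X = _impute_dosage(geno)
    return y, C, X


def _reml_neg_loglik(log_delta: float, s: np.ndarray, Uty: np.ndarray,
                     UtC: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = s + delta
    Cw = UtC / w[:, None]
    A = UtC.T @ Cw
    rhs = Cw.T @ Uty
    try:
        alpha = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return np.inf
    r = Uty - UtC @ alpha
    n, p = UtC.shape
    rss = float(r @ (r / w))
    if rss <= 0:
        return np.inf
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(w)) + logdetA
                 + (n - p))
    return -ll


def mlm_scan(trait: pd.Series, geno: GenotypeMatrix,
             Q: pd.DataFrame | None, K: pd.DataFrame) -> pd.DataFrame:
    """EMMAX-style mixed-model scan under a kinship random effect.

    The variance ratio is estimated once on the null model (REML via a log
    grid over delta in [1e-5, 1e5] refined by bounded minimization); every
    SNP is then tested by GLS under the fitted covariance. With K = I the
    scan reduces to the GLM.
    """
    y, C, X = _align(trait, geno, Q)
    Kv = K.reindex(index=geno.accession_ids, columns=geno.accession_ids).to_numpy(dtype=float)
    if np.isnan(Kv).any():
        raise ValueError("kinship rows missing for some accessions")
    Kv = (Kv + Kv.T) / 2.0
    s, U = np.linalg.eigh(Kv)
    if s.min() < -1e-8 * max(1.0, abs(s.max())):
        raise ValueError("kinship matrix is not positive semi-definite")
    s = np.maximum(s, 0.0)
    Uty = U.T @ y
    UtC = U.T @ C
    grid = np.linspace(np.log(1e-5), np.log(1e5), 100)
    vals = np.array([_reml_neg_loglik(g, s, Uty, UtC) for g in grid])
    if not np.isfinite(vals).any():
        # degenerate variance structure: fall back to OLS
        beta, se, p = _residual_scan(y, C, X)
        out = _scan_frame(geno, beta, se, p, "MLM")
        out["fallback_glm"] = True
        return out
    g0 = grid[int(np.nanargmin(vals))]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(g0 - 2.0, g0 + 2.0), method="bounded",
        args=(s, Uty, UtC))
    delta = float(np.exp(res.x if np.isfinite(res.fun) else g0))
    w = s + delta
    sw = np.sqrt(w)
    ystar = Uty / sw
    Cstar = UtC / sw[:, None]
    Xstar = (U.T @ X) / sw[:, None]
    beta, se, p = _residual_scan(ystar, Cstar, Xstar)
    return _scan_frame(geno, beta, se, p, "MLM")


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic-control lambda: median association chi2 over its null median."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / sps.chi2.ppf(0.5, df=1))


def candidate_genes(significant_snps: pd.DataFrame, annotation: pd.DataFrame,
                    flank: int = 50_000) -> pd.DataFrame:
    """Genes whose span lies within ``flank`` bp of a significant SNP.

    Distance is from the SNP position to the nearest gene edge (0 if the SNP
    falls inside the span); genes at exactly ``flank`` are included. The
    relative position labels where the gene lies with respect to the SNP
    coordinate (strand is not consulted).
    """
    rows = []
    seen = set()
    for snp in significant_snps.itertuples(index=False):
        hits = annotation[annotation["chrom"] == snp.chrom]
        for gene in hits.itertuples(index=False):
            if gene.start <= snp.pos <= gene.end:
                dist, rel = 0, "inside"
            elif snp.pos < gene.start:
                dist, rel = gene.start - snp.pos, "downstream"
            else:
                dist, rel = snp.pos - gene.end, "upstream"
            if dist <= flank and (snp.snp, gene.gene_id) not in seen:
                seen.add((snp.snp, gene.gene_id))
                rows.append({"gene_id": gene.gene_id, "snp": snp.snp,
                             "chrom": snp.chrom, "pos": snp.pos,
                             "distance": int(dist), "relative_position": rel})
    return pd.DataFrame(rows, columns=["gene_id", "snp", "chrom", "pos",
                                       "distance", "relative_position"])


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def genotype_class_test(geno: GenotypeMatrix, site_index: int,
                        trait: pd.Series) -> dict:
    """Trait distribution by genotype class at one SNP.

    Dosage classes are labelled with allele pairs from ref/alt (0 -> ref/ref
    etc.). Reports per-class trait means, sizes and germplasm-class
    composition, plus pairwise Welch t-tests; classes with fewer than two
    members are described but excluded from testing.
    """
    site = geno.sites.iloc[site_index]
    labels = {0.0: site["ref"] + site["ref"], 1.0: site["ref"] + site["alt"],
              2.0: site["alt"] + site["alt"]}
    dos = geno.dosage[:, site_index]
    trait = trait.reindex(geno.accession_ids)
    summary, classes = [], {}
    for d in (0.0, 1.0, 2.0):
        mask = dos == d
        if not mask.any():
            continue
        vals = trait.to_numpy()[mask]
        vals = vals[~np.isnan(vals)]
        types = pd.Series(np.array(geno.cultivar_type)[mask]).value_counts().to_dict()
        classes[labels[d]] = vals
        summary.append({"class": labels[d], "n": int(mask.sum()),
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "type_counts": types})
    tests = []
    names = list(classes)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = classes[names[i]], classes[names[j]]
            if len(a) < 2 or len(b) < 2:
                continue
            if a.var() == 0 and b.var() == 0:
                # degenerate Welch: equal constants are indistinguishable
                t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            else:
                t, p = sps.ttest_ind(a, b, equal_var=False)
            tests.append({"class1": names[i], "class2": names[j],
                          "t": float(t), "p": float(p), "sig": _stars(p)})
    return {"classes": pd.DataFrame(summary), "tests": pd.DataFrame(tests)}
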