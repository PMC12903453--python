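"""Rooting-ability phenotype analysis.

Covers the trait-level summary statistics, best linear unbiased estimates
(BLUEs) across years, broad-sense heritability from a two-way ANOVA variance
decomposition, trait PCA on BLUEs, and the membership-function composite
rooting score

    D = sum_j U_j * W_j,

where for each retained principal component j the comprehensive indicator
value CI_j is the accession's component score, the membership value
U_j = (CI_j - min CI_j) / (max CI_j - min CI_j) rescales it to [0, 1] over
the panel, and the weight W_j is that component's share of variance among the
retained components. Broad-sense heritability on an entry-mean basis is

    H^2 = Vg / (Vg + Vge / l + Ve / (r * l)),

with l environments (years) and r replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import TRAITS


@dataclass
class TraitStats:
    """Per trait-by-year summaries plus per-year trait correlation matrices."""

    summary: pd.DataFrame  # columns: trait, year, n, min, max, mean, sd, cv, skewness, kurtosis
    correlations: dict[str, pd.DataFrame]  # year -> trait x trait Pearson r
    correlation_pvalues: dict[str, pd.DataFrame]


@dataclass
class PCAResult:
    loadings: pd.DataFrame      # trait x component, orthonormal columns
    scores: pd.DataFrame        # accession x component
    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray


@dataclass
class RootingScore:
    ci: pd.DataFrame            # accession x retained component scores
    membership: pd.DataFrame    # U values in [0, 1]
    weights: pd.Series          # W per retained component, sums to 1
    d: pd.Series                # composite score per accession
    n_retained: int


def _accession_means(pheno: pd.DataFrame, year: str | None = None) -> pd.DataFrame:
    df = pheno if year is None else pheno[pheno["year"] == year]
    return df.groupby("accession", sort=True)[list(TRAITS)].mean()


def describe_traits(pheno: pd.DataFrame) -> TraitStats:
    """Descriptive statistics per trait and year, on per-accession means.

    SD is the sample (n-1) standard deviation, CV = 100*SD/mean, and kurtosis
    is excess kurtosis (normal = 0). Correlations are Pearson, on the same
    per-accession means, with two-sided p-values.
    """
    rows = []
    cors, pvals = {}, {}
    for year in sorted(pheno["year"].unique()):
        means = _accession_means(pheno, year)
        for trait in TRAITS:
            x = means[trait].dropna().to_numpy()
            if x.size < 2:
                warnings.warn(f"trait {trait} in {year} has < 2 observations", stacklevel=2)
                rows.append({"trait": trait, "year": year, "n": x.size,
                             "min": np.nan, "max": np.nan, "mean": np.nan,
                             "sd": np.nan, "cv": np.nan,
                             "skewness": np.nan, "kurtosis": np.nan})
                continue
            sd = x.std(ddof=1)
            rows.append({
                "trait": trait, "year": year, "n": x.size,
                "min": x.min(), "max": x.max(), "mean": x.mean(), "sd": sd,
                "cv": 100.0 * sd / x.mean() if x.mean() != 0 else np.nan,
                "skewness": sps.skew(x, bias=False),
                "kurtosis": sps.kurtosis(x, bias=False),  # excess
            })
        k = len(TRAITS)
        r = np.eye(k)
        p = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                pair = means[[TRAITS[i], TRAITS[j]]].dropna()
                if len(pair) >= 3:
                    rr, pp = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                else:
                    rr, pp = np.nan, np.nan
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
        cors[year] = pd.DataFrame(r, index=list(TRAITS), columns=list(TRAITS))
        pvals[year] = pd.DataFrame(p, index=list(TRAITS), columns=list(TRAITS))
    return TraitStats(pd.DataFrame(rows), cors, pvals)


def estimate_blues(pheno: pd.DataFrame,
                   variance_components: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-accession BLUEs across years and replicates, one column per trait.

    Model: genotype fixed, year random, replicate error residual. The
    genotype effects are the generalized-least-squares solution under
    V = s2_year * Z Z' + s2_e * I; for a balanced complete design this equals
    the plain genotype mean. Year and residual variances are estimated by
    method of moments from the year ANOVA unless supplied as
    ``variance_components = (s2_year, s2_e)``.
    """
    accessions = sorted(pheno["accession"].unique())
    years = sorted(pheno["year"].unique())
    out = pd.DataFrame(index=pd.Index(accessions, name="accession"),
                       columns=list(TRAITS), dtype=float)
    for trait in TRAITS:
        df = pheno[["accession", "year", trait]].dropna(subset=[trait])
        if df.empty:
            warnings.warn(f"trait {trait} has no observations", stacklevel=2)
            continue
        present = df.groupby("accession").size()
        dropped = set(accessions) - set(present.index)
        if dropped:
            warnings.warn(f"accessions with no {trait} data dropped: {sorted(dropped)[:5]}",
                          stacklevel=2)
        acc_idx = pd.Categorical(df["accession"], categories=sorted(present.index)).codes
        yr_idx = pd.Categorical(df["year"], categories=years).codes
        y = df[trait].to_numpy(dtype=float)
        n, g, l = len(y), len(present.index), len(years)
        X = np.zeros((n, g))
        X[np.arange(n), acc_idx] = 1.0
        if variance_components is None:
            # method-of-moments: residual MS after genotype+year fixed fit,
            # year variance from the year mean square
            Z = np.zeros((n, l))
            Z[np.arange(n), yr_idx] = 1.0
            XF = np.hstack([X, Z[:, 1:]])
            beta, *_ = np.linalg.lstsq(XF, y, rcond=None)
            resid = y - XF @ beta
            dfe = max(n - np.linalg.matrix_rank(XF), 1)
            s2e = float(resid @ resid) / dfe
            year_means = np.array([y[yr_idx == j].mean() for j in range(l)])
            counts = np.array([(yr_idx == j).sum() for j in range(l)])
            if l > 1:
                ms_year = float(np.sum(counts * (year_means - y.mean()) ** 2) / (l - 1))
                s2y = max((ms_year - s2e) / max(counts.mean(), 1.0), 0.0)
            else:
                s2y = 0.0
        else:
            s2y, s2e = variance_components
        s2e = max(s2e, 1e-8)  # keep V invertible for saturated toy designs
        Z = np.zeros((n, l))
        Z[np.arange(n), yr_idx] = 1.0
        V = s2y * (Z @ Z.T) + s2e * np.eye(n)
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        out.loc[sorted(present.index), trait] = beta
    return out


def h2_from_components(vg: float, vge: float, ve: float, l: int, r: float) -> float:
    """Entry-mean broad-sense heritability H2 = Vg/(Vg + Vge/l + Ve/(r*l))."""
    denom = vg + vge / l + ve / (r * l)
    return vg / denom if denom > 0 else 0.0


def variance_components_h2(pheno: pd.DataFrame) -> pd.DataFrame:
    """ANOVA method-of-moments variance components and broad-sense H2.

    Expected mean squares of the genotype-by-environment two-way layout give
    Ve = MS_error, Vge = (MS_GxE - MS_error)/r, Vg = (MS_G - MS_GxE)/(r*l).
    Negative moment estimates are truncated to 0 and flagged. With a single
    environment Vge is inestimable and H2 = Vg/(Vg + Ve/r).
    """
    years = sorted(pheno["year"].unique())
    l = len(years)
    rows = []
    for trait in TRAITS:
        df = pheno[["accession", "year", trait]].dropna(subset=[trait])
        cell = df.groupby(["accession", "year"])[trait]
        cell_means = cell.mean().unstack("year")
        cell_counts = cell.size().unstack("year")
        r = float(cell_counts.stack().mean())
        g = cell_means.shape[0]
        y = df[trait].to_numpy(dtype=float)
        grand = y.mean()
        geno_means = cell_means.mean(axis=1)
        env_means = cell_means.mean(axis=0)
        ms_err_num = ((df[trait] - cell.transform("mean")) ** 2).sum()
        df_err = len(df) - g * l
        ve = float(ms_err_num / df_err) if df_err > 0 else 0.0
        truncated = False
        if l >= 2:
            ms_g = r * l * float(((geno_means - grand) ** 2).sum()) / (g - 1)
            inter = cell_means.sub(geno_means, axis=0).sub(env_means, axis=1) + grand
            ms_ge = r * float((inter ** 2).sum().sum()) / ((g - 1) * (l - 1))
            vge = (ms_ge - ve) / r
            vg = (ms_g - ms_ge) / (r * l)
            if vge < 0:
                vge, truncated = 0.0, True
            if vg < 0:
                vg, truncated = 0.0, True
            h2 = h2_from_components(vg, vge, ve, l, r)
        else:
            ms_g = r * float(((geno_means - grand) ** 2).sum()) / (g - 1)
            vg = (ms_g - ve) / r
            if vg < 0:
                vg, truncated = 0.0, True
            vge = np.nan
            denom = vg + ve / r
            h2 = vg / denom if denom > 0 else 0.0
        rows.append({"trait": trait, "Vg": vg, "Vge": vge, "Ve": ve,
                     "l": l, "r": r, "H2": min(max(h2, 0.0), 1.0),
                     "truncated": truncated})
    return pd.DataFrame(rows).set_index("trait")


def trait_pca(blues: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of the trait BLUEs.

    Traits are standardized before decomposition, so the result is invariant
    to affine rescaling of any trait. Sign convention: in each component the
    largest-magnitude loading is positive.
    """
    blues = blues.dropna(axis=0, how="any")
    if blues.shape[1] < 2 or blues.shape[0] < 3:
        raise ValueError("need >= 2 traits and >= 3 accessions")
    sd = blues.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant traits cannot be standardized: {constant}")
    Z = (blues - blues.mean()) / sd
    n = Z.shape[0]
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    loadings = vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z.to_numpy() @ loadings
    prop = eigvals / eigvals.sum()
    comp = [f"PC{i + 1}" for i in range(len(eigvals))]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=blues.columns, columns=comp),
        scores=pd.DataFrame(scores, index=blues.index, columns=comp),
        eigenvalues=eigvals,
        proportion=prop,
        cumulative=np.cumsum(prop),
    )


def composite_rooting_score(pca: PCAResult,
                            retention_rule: tuple[str, float] = ("eigenvalue", 1.0),
                            ) -> RootingScore:
    """Membership-function composite score from retained components.

    ``retention_rule`` is ``("eigenvalue", floor)`` (keep components with
    eigenvalue > floor; default 1), ``("cumulative", tau)`` (smallest leading
    set reaching cumulative variance tau), or ``("fixed", n)``.
    """
    kind, value = retention_rule
    if kind == "eigenvalue":
        keep = np.flatnonzero(pca.eigenvalues > value)
    elif kind == "cumulative":
        keep = np.arange(int(np.searchsorted(pca.cumulative, value) + 1))
    elif kind == "fixed":
        keep = np.arange(int(value))
    else:
        raise ValueError(f"unknown retention rule {kind!r}")
    if keep.size == 0:
        keep = np.array([0])
    cols = [pca.scores.columns[j] for j in keep]
    ci = pca.scores[cols].copy()
    rng = ci.max() - ci.min()
    degenerate = rng[rng == 0].index.tolist()
    if degenerate:
        warnings.warn(f"components with zero score range dropped: {degenerate}",
                      stacklevel=2)
        cols = [c for c in cols if c not in degenerate]
        if not cols:
            raise ValueError("no retained component has positive score range")
        ci = ci[cols]
    keep = np.array([pca.scores.columns.get_loc(c) for c in cols])
    u = (ci - ci.min()) / (ci.max() - ci.min())
    w = pd.Series(pca.proportion[keep], index=cols)
    w = w / w.sum()
    d = (u * w).sum(axis=1)
    return RootingScore(ci=ci, membership=u, weights=w, d=d, n_retained=len(cols))


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_group_scores(d: pd.Series, labels: pd.Series) -> dict:
    """Group means/ranges of D plus pairwise Welch two-sided t-tests."""
    labels = labels.reindex(d.index)
    groups = sorted(labels.dropna().unique())
    summary = []
    for gname in groups:
        x = d[labels == gname]
        summary.append({"group": gname, "n": len(x), "mean_D": x.mean(),
                        "min_D": x.min(), "max_D": x.max()})
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = d[labels == groups[i]], d[labels == groups[j]]
            if len(a) < 2 or len(b) < 2:
                pairs.append({"group1": groups[i], "group2": groups[j],
                              "t": np.nan, "p": np.nan, "sig": "skipped"})
                continue
            t, p = sps.ttest_ind(a, b, equal_var=False)
            pairs.append({"group1": groups[i], "group2": groups[j],
                          "t": float(t), "p": float(p), "sig": _stars(p)})
    return {"groups": pd.DataFrame(summary), "tests": pd.DataFrame(pairs)}
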