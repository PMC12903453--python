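"""Expression normalization, differential expression, and co-expression modules.

The module pipeline follows the weighted co-expression network recipe:
genes are filtered to the top median-absolute-deviation fraction, an unsigned
adjacency |r|^beta is raised to the smallest soft power giving an
approximately scale-free connectivity distribution (fit R^2 >= 0.85),
topological overlap is clustered by average linkage, the tree is cut
statically with a minimum module size, and modules whose eigengenes correlate
above 0.7 are merged. Module eigengenes are first principal components of the
standardized module expression, sign-anchored so mean gene–eigengene
correlation is positive.

The differential-expression test is an explicit simplification (Welch t-test
on log2 normalized counts with Benjamini–Hochberg adjustment); the
classification thresholds — padj <= 0.05 and |log2FC| >= 1 — are exact, and
``classify_de`` can be applied to an externally computed DE table to preserve
fidelity when a negative-binomial analysis is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


@dataclass
class ModuleAssignment:
    modules: pd.Series            # gene -> module label ("unassigned" for leftovers)
    beta: int
    scale_free_r2: pd.Series      # candidate beta -> signed fit R^2
    beta_fallback: bool
    module_sizes: pd.Series


@dataclass
class ModuleTraitStats:
    eigengenes: pd.DataFrame      # samples x modules, unit variance
    var_explained: pd.Series      # per module, eigengene share of module variance
    module_trait_r: pd.DataFrame  # modules x traits
    module_trait_p: pd.DataFrame
    gs: pd.DataFrame              # genes x traits (gene significance)
    mm: pd.Series                 # gene -> correlation with own module eigengene
    modules: pd.Series


def normalize_fpkm(counts: np.ndarray | pd.DataFrame,
                   gene_lengths: np.ndarray) -> np.ndarray | pd.DataFrame:
    """FPKM = counts * 1e9 / (gene length in bp * library size)."""
    vals = np.asarray(counts, dtype=float)
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive total counts")
    lengths = np.asarray(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    fpkm = vals * 1e9 / (lengths[:, None] * lib[None, :])
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)
    return fpkm


def classify_de(table: pd.DataFrame, padj_max: float = 0.05,
                lfc_min: float = 1.0) -> pd.DataFrame:
    """Label genes up/down/ns from log2fc and padj columns (inclusive cuts)."""
    out = table.copy()
    sig = out["padj"] <= padj_max
    out["direction"] = np.where(sig & (out["log2fc"] >= lfc_min), "up",
                                np.where(sig & (out["log2fc"] <= -lfc_min),
                                         "down", "ns"))
    return out


def de_test(expr: ExpressionMatrix) -> pd.DataFrame:
    """Simplified strong-vs-weak differential expression.

    log2FC uses group means of library-size-normalized counts (counts per
    million) with a 0.5 pseudocount; the p-value is a Welch t-test on
    log2(CPM + 1); padj is Benjamini–Hochberg.
    """
    groups = np.asarray(expr.sample_group)
    for g in ("strong", "weak"):
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {g!r}")
    counts = expr.counts.astype(float)
    cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
    strong = cpm[:, groups == "strong"]
    weak = cpm[:, groups == "weak"]
    log2fc = np.log2(strong.mean(axis=1) + 0.5) - np.log2(weak.mean(axis=1) + 0.5)
    ls, lw = np.log2(strong + 1.0), np.log2(weak + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        t, p = sps.ttest_ind(ls, lw, axis=1, equal_var=False)
    all_zero = counts.sum(axis=1) == 0
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"gene_id": expr.gene_ids, "log2fc": log2fc,
                        "p": p, "padj": padj, "all_zero": all_zero})
    out = classify_de(out)
    out.loc[out["all_zero"], "direction"] = "ns"
    return out


def mad_filter(expression: pd.DataFrame, fraction: float = 0.30) -> pd.DataFrame:
    """Keep the ceil(fraction * G) genes with the largest MAD across samples.

    Ties are broken by gene order in the input (stable sort).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    mad = (expression.sub(expression.median(axis=1), axis=0)).abs().median(axis=1)
    k = int(np.ceil(fraction * len(expression)))
    order = np.argsort(-mad.to_numpy(), kind="stable")[:k]
    return expression.iloc[np.sort(order)]


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency fit (WGCNA style)."""
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = sps.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def _default_power(n_samples: int) -> int:
    """Unsigned-network soft powers conventionally used per sample size."""
    if n_samples < 20:
        return 10
    if n_samples < 30:
        return 9
    if n_samples < 40:
        return 8
    return 7


def pick_soft_threshold(expression: pd.DataFrame, betas: range = range(1, 21),
                        r2_floor: float = 0.85) -> tuple[int, pd.Series, bool]:
    """Smallest beta whose scale-free fit reaches the floor.

    If no candidate reaches the floor (common when the network is strongly
    modular rather than scale-free), the conventional sample-size-based
    unsigned power is used and the fallback is flagged.
    """
    corr = np.corrcoef(expression.to_numpy())
    np.fill_diagonal(corr, 0.0)
    acorr = np.abs(corr)
    fits = {}
    for b in betas:
        k = (acorr ** b).sum(axis=1)
        fits[b] = _scale_free_r2(k)
    fits = pd.Series(fits)
    ok = fits[fits >= r2_floor]
    if len(ok):
        return int(ok.index[0]), fits, False
    return _default_power(expression.shape[1]), fits, True


def _tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return 1.0 - tom


def _eigengene(block: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Unit-variance first PC of standardized genes-x-samples expression."""
    Z = block.sub(block.mean(axis=1), axis=0)
    sd = block.std(axis=1, ddof=1).replace(0.0, np.nan)
    Z = Z.div(sd, axis=0).dropna(axis=0).to_numpy()
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    # anchor: mean correlation of genes with eigengene positive
    if np.mean([np.corrcoef(row, e)[0, 1] for row in Z]) < 0:
        e = -e
    e = (e - e.mean()) / e.std(ddof=1)
    return e, var_explained


def build_network_modules(expression: pd.DataFrame,
                          min_module_size: int = 30,
                          cut_height: float = 0.995,
                          merge_correlation: float = 0.7,
                          r2_floor: float = 0.85) -> ModuleAssignment:
    """Detect co-expression modules from a genes-x-samples expression table.

    The dendrogram is cut statically at ``cut_height`` on the topological-
    overlap dissimilarity scale (default 0.995: unrelated genes sit at
    dissimilarity ~1, co-expressed blocks well below). Modules whose
    eigengene Pearson correlation exceeds ``merge_correlation`` are merged
    iteratively. Genes in clusters smaller than ``min_module_size`` are
    labelled ``unassigned``.
    """
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if expression.shape[0] < 2 * min_module_size:
        raise ValueError("need >= 2 * min_module_size genes")
    beta, fits, fallback = pick_soft_threshold(expression, r2_floor=r2_floor)
    if fallback:
        warnings.warn(f"no soft power reached scale-free R^2 {r2_floor}; "
                      f"using beta={beta}", stacklevel=2)
    corr = np.corrcoef(expression.to_numpy())
    adjacency = np.abs(corr) ** beta
    diss = _tom_dissimilarity(adjacency)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    modules = pd.Series("unassigned", index=expression.index, dtype=object)
    next_id = 1
    for lab in pd.unique(labels):
        sel = labels == lab
        if sel.sum() >= min_module_size:
            modules.iloc[np.flatnonzero(sel)] = f"M{next_id}"
            next_id += 1
    # iterative eigengene merging
    while True:
        names = [m for m in pd.unique(modules) if m != "unassigned"]
        if len(names) < 2:
            break
        eig = {m: _eigengene(expression.loc[modules == m])[0] for m in names}
        best, pair = merge_correlation, None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = abs(np.corrcoef(eig[names[i]], eig[names[j]])[0, 1])
                if r > best:
                    best, pair = r, (names[i], names[j])
        if pair is None:
            break
        modules[modules == pair[1]] = pair[0]
    sizes = modules[modules != "unassigned"].value_counts()
    return ModuleAssignment(modules=modules, beta=beta, scale_free_r2=fits,
                            beta_fallback=fallback, module_sizes=sizes)


def module_trait_stats(expression: pd.DataFrame, modules: pd.Series,
                       traits: pd.DataFrame) -> ModuleTraitStats:
    """Eigengenes, module–trait correlations, gene significance, membership.

    ``traits`` is samples x trait-values aligned with the expression columns.
    GS is the gene–trait Pearson correlation; MM is the gene's correlation
    with its own module's eigengene. Constant traits yield missing values
    with a warning.
    """
    traits = traits.reindex(expression.columns)
    names = [m for m in pd.unique(modules) if m != "unassigned"]
    if not names:
        raise ValueError("no modules to analyse")
    eig, varex = {}, {}
    for m in names:
        eig[m], varex[m] = _eigengene(expression.loc[modules == m])
    eigengenes = pd.DataFrame(eig, index=expression.columns)
    r_rows, p_rows = {}, {}
    n = len(expression.columns)
    for t in traits.columns:
        tv = traits[t].to_numpy(dtype=float)
        if np.nanstd(tv) == 0:
            warnings.warn(f"trait {t} is constant; correlations undefined",
                          stacklevel=2)
            r_rows[t] = {m: np.nan for m in names}
            p_rows[t] = {m: np.nan for m in names}
            continue
        r_rows[t], p_rows[t] = {}, {}
        for m in names:
            r, p = sps.pearsonr(eigengenes[m], tv)
            r_rows[t][m] = r
            p_rows[t][m] = p
    expr_z = expression.sub(expression.mean(axis=1), axis=0)
    expr_sd = expression.std(axis=1, ddof=1)
    gs = {}
    for t in traits.columns:
        tv = traits[t].to_numpy(dtype=float)
        sd = np.nanstd(tv)
        if sd == 0:
            gs[t] = pd.Series(np.nan, index=expression.index)
            continue
        tz = (tv - tv.mean()) / tv.std(ddof=1)
        cov = expr_z.to_numpy() @ tz / (n - 1)
        gs[t] = pd.Series(cov / expr_sd.to_numpy(), index=expression.index)
    mm = pd.Series(np.nan, index=expression.index)
    for m in names:
        block = expression.loc[modules == m]
        bz = block.sub(block.mean(axis=1), axis=0)
        bsd = block.std(axis=1, ddof=1)
        ez = (eigengenes[m] - eigengenes[m].mean()) / eigengenes[m].std(ddof=1)
        cov = bz.to_numpy() @ ez.to_numpy() / (n - 1)
        mm.loc[block.index] = cov / bsd.to_numpy()
    return ModuleTraitStats(
        eigengenes=eigengenes,
        var_explained=pd.Series(varex),
        module_trait_r=pd.DataFrame(r_rows).loc[names],
        module_trait_p=pd.DataFrame(p_rows).loc[names],
        gs=pd.DataFrame(gs),
        mm=mm,
        modules=modules,
    )


def hub_genes(stats: ModuleTraitStats, gs_min: float = 0.2, mm_min: float = 0.8,
              module_traits: dict[str, str] | None = None) -> dict[str, list[str]]:
    """Hub genes per module: |GS| > gs_min and |MM| > mm_min (strict).

    GS is evaluated against each module's designated trait — by default the
    trait most correlated with the module eigengene.
    """
    out: dict[str, list[str]] = {}
    for m in stats.module_trait_r.index:
        if module_traits and m in module_traits:
            t = module_traits[m]
        else:
            r = stats.module_trait_r.loc[m].abs()
            if r.isna().all():
                out[m] = []
                continue
            t = r.idxmax()
        members = stats.modules[stats.modules == m].index
        sel = (stats.gs.loc[members, t].abs() > gs_min) & (stats.mm[members].abs() > mm_min)
        out[m] = list(members[sel])
    return out
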