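"""Windowed diversity and differentiation statistics and the sweep caller.

The selective-sweep scan contrasts a putatively selected (improved) germplasm
group against an unselected one: Weir–Cockerham (1984) F_ST between the two
groups and the nucleotide-diversity ratio pi_unselected / pi_selected are
computed in sliding windows (100 kb window, 10 kb step by default), and
windows in the top 5% of both distributions are merged into candidate sweep
intervals.

Conventions, fixed for reproducibility:

* per-site pi is the unbiased mean pairwise difference
  2 * n_ref * n_alt / (n * (n - 1)) over non-missing alleles; the window
  value divides the site sum by the window span in bp (monomorphic positions
  contribute zero implicitly);
* window F_ST is the ratio-of-sums ("weighted") Weir–Cockerham estimator,
  sum(a) / sum(a + b + c); negative values are retained so quantiles are
  honest;
* quantile thresholds use numpy's linear interpolation between order
  statistics;
* windows sharing >= 1 bp or exactly abutting are merged.

Coordinates are 1-based inclusive throughout; BED export converts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix


@dataclass
class StructureResult:
    """Genotype PCA coordinates, VanRaden kinship, and optional NJ tree."""

    pcs: pd.DataFrame            # accession x component, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray
    kinship: pd.DataFrame        # accession x accession, symmetric
    newick: str | None = None


# ---------------------------------------------------------------------------
# per-site statistics

def _site_pi(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased pi and a usable-site mask for one group."""
    present = ~np.isnan(dosage)
    n = 2.0 * present.sum(axis=0)
    n_alt = np.nansum(dosage, axis=0)
    usable = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * n_alt * (n - n_alt) / (n * (n - 1.0))
    pi = np.where(usable, pi, 0.0)
    return pi, usable


def _site_fst_components(dos_a: np.ndarray, dos_b: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) per-site variance components a, b, c for 2 pops.

    Observed heterozygosity comes from dosage-1 genotypes. Sites where either
    population has no data, or with fewer than 2 genotypes overall, are
    flagged unusable.
    """
    comps = []
    ns, ps, hs = [], [], []
    for dos in (dos_a, dos_b):
        present = ~np.isnan(dos)
        n_i = present.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(dos, axis=0) / (2.0 * n_i)
            h_i = np.nansum(dos == 1.0, axis=0) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    usable &= (nbar > 1) & (nc > 0)
    zero = ~usable
    for arr in (a, b, c):
        arr[zero] = 0.0
    return a, b, c, usable


# ---------------------------------------------------------------------------
# windows

def _window_grid(chrom_length: int, window_bp: int, step_bp: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(1, chrom_length + 1, step_bp)
    ends = np.minimum(starts + window_bp - 1, chrom_length)
    return starts, ends


def _chrom_lengths(geno: GenotypeMatrix,
                   chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    if chrom_lengths is not None:
        return chrom_lengths
    return {c: int(g["pos"].max())
            for c, g in geno.sites.groupby("chrom", sort=False)}


def _windowed_ratio(geno: GenotypeMatrix, numer: np.ndarray, denom: np.ndarray | None,
                    usable: np.ndarray, window_bp: int, step_bp: int,
                    lengths: dict[str, int], kind: str, per_bp: bool) -> pd.DataFrame:
    """Aggregate per-site sums into sliding windows via prefix sums."""
    out = []
    for chrom, grp in geno.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        starts, ends = _window_grid(lengths[chrom], window_bp, step_bp)
        cn = np.concatenate([[0.0], np.cumsum(numer[idx])])
        cd = (np.concatenate([[0.0], np.cumsum(denom[idx])])
              if denom is not None else None)
        cu = np.concatenate([[0], np.cumsum(usable[idx].astype(int))])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        num = cn[hi] - cn[lo]
        n_snps = cu[hi] - cu[lo]
        if per_bp:
            value = num / (ends - starts + 1)
        else:
            den = cd[hi] - cd[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                value = np.where((n_snps > 0) & (den != 0), num / den, np.nan)
        out.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                 "n_snps": n_snps, "value": value, "kind": kind}))
    return pd.concat(out, ignore_index=True)


def window_pi(geno: GenotypeMatrix, group_mask: np.ndarray,
              window_bp: int = 100_000, step_bp: int = 10_000,
              chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sliding-window nucleotide diversity (per bp) within one group."""
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window and step must be positive")
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.sum() < 2:
        raise ValueError("group must contain >= 2 accessions")
    lengths = _chrom_lengths(geno, chrom_lengths)
    pi, usable = _site_pi(geno.dosage[group_mask])
    return _windowed_ratio(geno, pi, None, usable, window_bp, step_bp,
                           lengths, "pi", per_bp=True)


def window_fst(geno: GenotypeMatrix, group_a: np.ndarray, group_b: np.ndarray,
               window_bp: int = 100_000, step_bp: int = 10_000,
               chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sliding-window weighted Weir–Cockerham F_ST between two groups."""
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if group_a.sum() < 2 or group_b.sum() < 2:
        raise ValueError("both groups need >= 2 accessions")
    lengths = _chrom_lengths(geno, chrom_lengths)
    a, b, c, usable = _site_fst_components(geno.dosage[group_a], geno.dosage[group_b])
    return _windowed_ratio(geno, a, a + b + c, usable, window_bp, step_bp,
                           lengths, "fst", per_bp=False)


def pi_ratio(pi_a: pd.DataFrame, pi_b: pd.DataFrame, min_snps: int = 10) -> pd.DataFrame:
    """Per-window diversity ratio pi_A / pi_B on aligned window grids.

    Windows where pi_B is zero, or where either group has fewer than
    ``min_snps`` usable sites, are set missing (excluded from quantiles).
    """
    key = ["chrom", "start", "end"]
    if len(pi_a) != len(pi_b) or not (pi_a[key].values == pi_b[key].values).all():
        raise ValueError("window lists must be aligned on identical coordinates")
    out = pi_a[key].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = pi_a["value"].to_numpy() / pi_b["value"].to_numpy()
    bad = ((pi_b["value"].to_numpy() == 0)
           | (pi_a["n_snps"].to_numpy() < min_snps)
           | (pi_b["n_snps"].to_numpy() < min_snps))
    out["n_snps"] = np.minimum(pi_a["n_snps"], pi_b["n_snps"])
    out["value"] = np.where(bad, np.nan, ratio)
    out["kind"] = "pi_ratio"
    return out


def call_sweeps(fst_windows: pd.DataFrame, ratio_windows: pd.DataFrame,
                quantile: float = 0.95,
                chrom_lengths: dict[str, int] | None = None,
                ) -> tuple[pd.DataFrame, float]:
    """Dual top-quantile sweep caller.

    A window is selected iff its F_ST and its pi-ratio both reach the
    empirical ``quantile`` of their non-missing distributions; selected
    windows that overlap or abut are merged into maximal intervals. Returns
    the interval table and the flagged genome fraction (interval bp over
    total chromosome bp).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    key = ["chrom", "start", "end"]
    if len(fst_windows) != len(ratio_windows) or not (
            fst_windows[key].values == ratio_windows[key].values).all():
        raise ValueError("window lists must be aligned on identical coordinates")
    f = fst_windows["value"].to_numpy(dtype=float)
    r = ratio_windows["value"].to_numpy(dtype=float)
    thr_f = np.quantile(f[~np.isnan(f)], quantile)
    thr_r = np.quantile(r[~np.isnan(r)], quantile)
    sel = (f >= thr_f) & (r >= thr_r) & ~np.isnan(f) & ~np.isnan(r)
    if chrom_lengths is None:
        chrom_lengths = {c: int(g["end"].max())
                         for c, g in fst_windows.groupby("chrom", sort=False)}
    total_bp = float(sum(chrom_lengths.values()))
    if not sel.any():
        cols = ["chrom", "start", "end", "mean_fst", "mean_pi_ratio", "n_windows"]
        return pd.DataFrame(columns=cols), 0.0
    win = fst_windows.loc[sel, key].copy()
    win["fst"] = f[sel]
    win["ratio"] = r[sel]
    rows = []
    for chrom, grp in win.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for t in grp.itertuples(index=False):
            if cur is not None and t.start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], t.end)
                cur["fst"].append(t.fst)
                cur["ratio"].append(t.ratio)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": t.start, "end": t.end,
                       "fst": [t.fst], "ratio": [t.ratio]}
        rows.append(cur)
    intervals = pd.DataFrame({
        "chrom": [r_["chrom"] for r_ in rows],
        "start": [int(r_["start"]) for r_ in rows],
        "end": [int(r_["end"]) for r_ in rows],
        "mean_fst": [float(np.mean(r_["fst"])) for r_ in rows],
        "mean_pi_ratio": [float(np.mean(r_["ratio"])) for r_ in rows],
        "n_windows": [len(r_["fst"]) for r_ in rows],
    })
    fraction = float((intervals["end"] - intervals["start"] + 1).sum()) / total_bp
    return intervals, fraction


def genes_in_intervals(intervals: pd.DataFrame, annotation: pd.DataFrame
                       ) -> list[list[str]]:
    """Gene ids overlapping each interval by >= 1 bp (1-based inclusive).

    A gene is assigned to at most one interval (the first, in table order,
    that it overlaps).
    """
    assigned: set[str] = set()
    out: list[list[str]] = []
    for iv in intervals.itertuples(index=False):
        hit = annotation[(annotation["chrom"] == iv.chrom)
                         & (annotation["start"] <= iv.end)
                         & (annotation["end"] >= iv.start)]
        ids = [g for g in hit["gene_id"] if g not in assigned]
        assigned.update(ids)
        out.append(ids)
    return out


def group_diversity_divergence(geno: GenotypeMatrix, labels: list[str] | np.ndarray,
                               chrom_lengths: dict[str, int] | None = None) -> dict:
    """Genome-wide pi per subgroup and pairwise ratio-of-sums F_ST."""
    labels = np.asarray(labels)
    lengths = _chrom_lengths(geno, chrom_lengths)
    total_bp = float(sum(lengths.values()))
    groups = []
    for gname in pd.unique(labels):
        if (labels == gname).sum() < 2:
            warnings.warn(f"singleton subgroup {gname!r} skipped", stacklevel=2)
            continue
        groups.append(gname)
    pi_rows = []
    for gname in groups:
        pi, _ = _site_pi(geno.dosage[labels == gname])
        pi_rows.append({"group": gname, "pi": float(pi.sum()) / total_bp})
    fst_rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b, c, usable = _site_fst_components(
                geno.dosage[labels == groups[i]], geno.dosage[labels == groups[j]])
            denom = float((a + b + c)[usable].sum())
            fst = float(a[usable].sum()) / denom if denom != 0 else np.nan
            fst_rows.append({"group1": groups[i], "group2": groups[j], "fst": fst})
    return {"pi": pd.DataFrame(pi_rows), "fst": pd.DataFrame(fst_rows)}


def genotype_pca_kinship(geno: GenotypeMatrix, k: int = 10) -> StructureResult:
    """VanRaden genomic relationship matrix and its top-k principal components.

    Missing dosages are mean-imputed per site; monomorphic sites are skipped.
    Each SNP column is centered at 2p and scaled by sqrt(2p(1-p)), so the
    mean diagonal of the kinship is ~1 under random mating.
    """
    X = geno.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < k:
        raise ValueError("fewer informative SNPs than requested components")
    X = X[:, poly]
    p = p[poly]
    W = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = (W @ W.T) / W.shape[1]
    K = (K + K.T) / 2.0
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.maximum(vals[order], 0.0)
    pcs = vecs[:, order] * np.sqrt(vals_k)
    idx = pd.Index(geno.accession_ids, name="accession")
    return StructureResult(
        pcs=pd.DataFrame(pcs, index=idx, columns=[f"PC{i+1}" for i in range(k)]),
        eigenvalues=vals_k,
        kinship=pd.DataFrame(K, index=idx, columns=geno.accession_ids),
    )


# ---------------------------------------------------------------------------
# neighbor joining

def ibs_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """1 - identity-by-state proportion between accession pairs."""
    X = geno.dosage
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i:])
        ok = ~np.isnan(diff)
        with np.errstate(invalid="ignore"):
            d = np.where(ok.sum(axis=1) > 0,
                         np.nansum(diff, axis=1) / (2.0 * ok.sum(axis=1)), 0.0)
        D[i, i:] = d
        D[i:, i] = d
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=geno.accession_ids, columns=geno.accession_ids)


def nj_tree(data: GenotypeMatrix | pd.DataFrame) -> str:
    """Saitou–Nei neighbor joining, returning a Newick string.

    Accepts a genotype matrix (distance = 1 - IBS proportion) or a symmetric
    distance DataFrame. Ties in the Q matrix are broken by the smallest index
    pair; negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch.
    """
    if isinstance(data, GenotypeMatrix):
        dm = ibs_distance(data)
    else:
        dm = data
    D = np.asarray(dm, dtype=float)
    names = list(dm.index)
    if D.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(D, D.T, atol=1e-10) or (np.diag(D) != 0).any() or (D < -1e-12).any():
        raise ValueError("distances must be symmetric, non-negative, zero-diagonal")

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.10g}"

    nodes = list(names)  # newick substrings for active nodes
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Qm = (m - 2) * D - R[:, None] - R[None, :]
        Qm[np.tril_indices(m)] = np.inf
        # flat argmin returns the first occurrence in row-major order, which
        # is exactly the smallest (i, j) pair on ties
        bi, bj = np.unravel_index(int(np.argmin(Qm)), Qm.shape)
        vi = D[bi, bj] / 2.0 + (R[bi] - R[bj]) / (2.0 * (m - 2))
        vj = D[bi, bj] - vi
        if vi < 0:
            vj, vi = vj + vi, 0.0
        if vj < 0:
            vi, vj = vi + vj, 0.0
        new = f"({nodes[bi]}:{fmt(vi)},{nodes[bj]}:{fmt(vj)})"
        dnew = 0.5 * (D[bi] + D[bj] - D[bi, bj])
        keep = [x for x in range(m) if x not in (bi, bj)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [new]
        D = D2
    # three-point star join
    va = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    vb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    vc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    return (f"({nodes[0]}:{fmt(va)},{nodes[1]}:{fmt(vb)},{nodes[2]}:{fmt(vc)});")
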