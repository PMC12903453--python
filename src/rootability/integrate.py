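"""Cross-stage integration, enrichment, qPCR relative expression, pipeline.

``run_pipeline`` wires the stages end to end on synthetic data: simulate ->
SNP filter -> composite scoring -> population structure -> sweep scan ->
GWAS -> co-expression -> candidate overlap, writing stage TSV/BED artifacts
and a machine-readable JSON summary. Everything is deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import coexpr, gwas, io, popgen, scoring, simulate
from .datatypes import TRAITS


def overlap_candidates(gene_sets: dict[str, list[str] | set[str]]) -> dict:
    """Pairwise and triple intersections of named gene sets.

    Gene order in the reported member lists is sorted for stability.
    """
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 named gene sets")
    sets = {k: set(v) for k, v in gene_sets.items()}
    names = list(sets)
    out = {"sets": {k: sorted(v) for k, v in sets.items()}, "pairs": {}, "triples": {}}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            inter = sorted(sets[names[i]] & sets[names[j]])
            out["pairs"][f"{names[i]}&{names[j]}"] = {"count": len(inter),
                                                      "genes": inter}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            for k in range(j + 1, len(names)):
                inter = sorted(sets[names[i]] & sets[names[j]] & sets[names[k]])
                key = f"{names[i]}&{names[j]}&{names[k]}"
                out["triples"][key] = {"count": len(inter), "genes": inter}
    return out


def hypergeom_enrichment(query_genes: list[str] | set[str],
                         universe: list[str] | set[str],
                         term_map: dict[str, list[str] | set[str]],
                         q_max: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    p = P(X >= k) for overlap k between the query (size n) and a term's gene
    set (size K) in a universe of size N; q is Benjamini–Hochberg across
    terms; terms with q <= ``q_max`` are flagged enriched.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in term_map.items():
        term_set = set(genes) & universe
        K = len(term_set)
        k = len(term_set & query)
        # P(X >= k); sf(k-1) includes k, and k = 0 gives p = 1
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["enriched"] = df["q"] <= q_max
    return df


def delta_delta_ct(ct_table: pd.DataFrame, reference_gene: str,
                   calibrator_sample: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct_table`` columns: sample, gene, ct (one row per technical replicate;
    replicates are averaged before differencing). dCt = Ct_target -
    Ct_reference per sample; ddCt subtracts the calibrator sample's dCt, so
    the calibrator's relative expression is exactly 1 for every target.
    """
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if calibrator_sample not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from table")
    keep = mean_ct[reference_gene].notna()
    dropped = mean_ct.index[~keep]
    if len(dropped):
        warnings.warn(f"samples without reference Ct skipped: {list(dropped)}",
                      stacklevel=2)
    mean_ct = mean_ct[keep]
    targets = [g for g in mean_ct.columns if g != reference_gene]
    rows = []
    for target in targets:
        dct = mean_ct[target] - mean_ct[reference_gene]
        ddct = dct - dct.loc[calibrator_sample]
        for sample in mean_ct.index:
            rows.append({"gene": target, "sample": sample,
                         "ct_target": mean_ct.loc[sample, target],
                         "ct_reference": mean_ct.loc[sample, reference_gene],
                         "delta_ct": dct.loc[sample],
                         "delta_delta_ct": ddct.loc[sample],
                         "relative_expression": 2.0 ** (-ddct.loc[sample])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline

DEFAULT_CONFIG: dict = {
    "n_accessions": 188,
    "subpop_sizes": [70, 59, 59],
    "chrom_lengths": {"Chr1": 1_000_000, "Chr2": 1_000_000, "Chr3": 1_000_000},
    "snp_density": 0.002,
    "base_fst": 0.05,
    "missing_rate": 0.02,
    "plant_sweeps": True,
    "sweep_delta_p": 0.6,
    "sweep_diversity_fold": 5.0,
    "n_causal_snps": 2,
    "causal_effect": 0.6,
    "n_genes_annotation": 300,
    "maf_min": 0.05,
    "missing_max": 0.20,
    "window_bp": 100_000,
    "step_bp": 10_000,
    "quantile": 0.95,
    "min_snps": 10,
    "flank": 50_000,
    "me": None,
    "gwas_traits": ["TL", "SA", "AD", "NR"],
    "nj_tree": False,
    "n_expression_genes": 400,
    "expression_module_sizes": [50, 50],
    "expression_loading": 0.9,
    "min_module_size": 30,
    "seed": 0,
}


def _simulate_annotation(chrom_lengths: dict[str, int], n_genes: int,
                         seed: int) -> pd.DataFrame:
    """Evenly tiled synthetic gene models with jittered spans."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    total = sum(chrom_lengths.values())
    gid = 1
    for chrom, length in chrom_lengths.items():
        k = max(int(round(n_genes * length / total)), 1)
        starts = np.linspace(1, length - 5000, k).astype(int)
        for s in starts:
            span = int(rng.integers(1000, 4000))
            rows.append({"gene_id": f"g{gid:04d}", "chrom": chrom,
                         "start": int(s), "end": min(int(s) + span, length),
                         "strand": "+" if rng.random() < 0.5 else "-"})
            gid += 1
    return pd.DataFrame(rows)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results",
                 seed: int | None = None) -> dict:
    """Run the full synthetic-data analysis and write stage artifacts.

    Returns the JSON-serializable summary (also written to ``summary.json``).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if seed is not None:
        cfg["seed"] = seed
    master = int(cfg["seed"])
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(master).spawn(4)]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_lengths = {k: int(v) for k, v in cfg["chrom_lengths"].items()}

    # --- simulate
    sweep_spec = (simulate.default_sweep_spec(
        chrom_lengths, delta_p=cfg["sweep_delta_p"],
        diversity_fold=cfg["sweep_diversity_fold"])
        if cfg["plant_sweeps"] else [])
    geno_raw, truth = simulate.simulate_genotypes(
        n_accessions=cfg["n_accessions"], subpop_sizes=tuple(cfg["subpop_sizes"]),
        chrom_lengths=chrom_lengths, snp_density=cfg["snp_density"],
        base_fst=cfg["base_fst"], sweep_spec=sweep_spec,
        missing_rate=cfg["missing_rate"], seed=seeds[0])
    annotation = _simulate_annotation(chrom_lengths, cfg["n_genes_annotation"], seeds[0])
    geno = simulate.filter_snps(geno_raw, cfg["maf_min"], cfg["missing_max"])

    # plant causal SNPs inside sweep regions where possible
    rng = np.random.default_rng(seeds[1])
    causal = []
    if cfg["n_causal_snps"]:
        in_sweep = np.zeros(geno.n_sites, dtype=bool)
        for chrom, s, e in truth.sweep_intervals:
            in_sweep |= ((geno.sites["chrom"] == chrom) & (geno.sites["pos"] >= s)
                         & (geno.sites["pos"] <= e)).to_numpy()
        pool = np.flatnonzero(in_sweep) if in_sweep.any() else np.arange(geno.n_sites)
        picks = rng.choice(pool, size=min(cfg["n_causal_snps"], pool.size),
                           replace=False)
        for idx in picks:
            causal.append((int(idx), {t: cfg["causal_effect"]
                                      for t in cfg["gwas_traits"]}))
    truth.causal_snps = causal
    pheno = simulate.simulate_phenotypes(geno, truth, seed=seeds[1])

    io.write_vcf(geno, out / "genotypes.vcf", chrom_lengths)
    io.write_groups_tsv(geno, out / "groups.tsv")
    io.write_phenotypes_tsv(pheno, out / "phenotypes.tsv")
    io.write_gff3(annotation, out / "genes.gff3")
    io.write_truth_json(truth, out / "truth.json")

    # --- scoring
    blues = scoring.estimate_blues(pheno)
    vc = scoring.variance_components_h2(pheno)
    pca = scoring.trait_pca(blues)
    score = scoring.composite_rooting_score(pca)
    types = pd.Series(geno.cultivar_type, index=geno.accession_ids)
    groups = scoring.compare_group_scores(score.d, types)
    blues.to_csv(out / "blues.tsv", sep="\t")
    vc.to_csv(out / "heritability.tsv", sep="\t")
    score.d.rename("D").to_csv(out / "rooting_score.tsv", sep="\t")
    groups["tests"].to_csv(out / "group_tests.tsv", sep="\t", index=False)

    # --- structure
    structure = popgen.genotype_pca_kinship(geno, k=10)
    Q = structure.pcs.iloc[:, : max(len(cfg["subpop_sizes"]) - 1, 1)]
    if cfg["nj_tree"]:
        newick = popgen.nj_tree(geno)
        (out / "nj_tree.nwk").write_text(newick + "\n")

    # --- sweep scan (TC vs SCC, as in a domestication contrast)
    mask_tc = geno.type_mask("TC")
    mask_scc = geno.type_mask("SCC")
    pi_tc = popgen.window_pi(geno, mask_tc, cfg["window_bp"], cfg["step_bp"],
                             chrom_lengths)
    pi_scc = popgen.window_pi(geno, mask_scc, cfg["window_bp"], cfg["step_bp"],
                              chrom_lengths)
    fst = popgen.window_fst(geno, mask_tc, mask_scc, cfg["window_bp"],
                            cfg["step_bp"], chrom_lengths)
    ratio = popgen.pi_ratio(pi_tc, pi_scc, cfg["min_snps"])
    intervals, genome_fraction = popgen.call_sweeps(fst, ratio, cfg["quantile"],
                                                    chrom_lengths)
    sweep_genes = sorted({g for lst in popgen.genes_in_intervals(intervals, annotation)
                          for g in lst})
    fst.to_csv(out / "windows_fst.tsv", sep="\t", index=False)
    ratio.to_csv(out / "windows_pi_ratio.tsv", sep="\t", index=False)
    intervals.to_csv(out / "sweep_intervals.tsv", sep="\t", index=False)
    if len(intervals):
        io.intervals_to_bed(intervals, out / "sweep_intervals.bed")
    diversity = popgen.group_diversity_divergence(
        geno, geno.cultivar_type, chrom_lengths)
    diversity["pi"].to_csv(out / "subgroup_pi.tsv", sep="\t", index=False)
    diversity["fst"].to_csv(out / "subgroup_fst.tsv", sep="\t", index=False)

    # --- GWAS. Without a supplied Me the threshold is plain Bonferroni over
    # the tested SNPs (me: "estimate" invokes the eigenvalue estimator, which
    # is rank-limited when accessions are far fewer than SNPs)
    if cfg["me"] == "estimate":
        thr = gwas.significance_threshold(geno)
    else:
        thr = gwas.significance_threshold(cfg["me"] or geno.n_sites)
    assoc_frames, sig_frames = [], []
    for t in cfg["gwas_traits"]:
        trait = blues[t]
        for fn, kwargs in ((gwas.glm_scan, {}), (gwas.mlm_scan, {"K": structure.kinship})):
            res = fn(trait, geno, Q, **kwargs)
            res.insert(0, "trait", t)
            assoc_frames.append(res)
            sig_frames.append(res[res["p"] <= thr.p_threshold])
    assoc = pd.concat(assoc_frames, ignore_index=True)
    sig = pd.concat(sig_frames, ignore_index=True)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    sig.to_csv(out / "significant_snps.tsv", sep="\t", index=False)
    sig_unique = sig.drop_duplicates("snp")
    cand = gwas.candidate_genes(sig_unique, annotation, cfg["flank"])
    cand.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    gwas_genes = sorted(cand["gene_id"].unique())

    # --- co-expression (module genes are mapped onto annotation gene ids so
    # the stages share a namespace)
    n_expr = min(cfg["n_expression_genes"], len(annotation))
    module_spec = [{"name": f"ME{i + 1}", "size": s, "loading": cfg["expression_loading"],
                    "log2fc": 2.0 if i == 0 else 0.0}
                   for i, s in enumerate(cfg["expression_module_sizes"])]
    trait_links = {"ME1": {"trait": "TL", "r": 0.8}}
    expr, expr_truth = simulate.simulate_expression(
        n_genes=n_expr, module_spec=module_spec, trait_links=trait_links,
        seed=seeds[2])
    # rename simulated genes to annotation ids (GWAS candidate genes first so
    # cross-stage overlaps are possible on synthetic data)
    preferred = [g for g in gwas_genes if g in set(annotation["gene_id"])]
    rest = [g for g in annotation["gene_id"] if g not in set(preferred)]
    id_map = dict(zip(expr.gene_ids, (preferred + rest)[:n_expr]))
    expr.gene_ids = [id_map[g] for g in expr.gene_ids]
    expr_truth.true_modules = {id_map[g]: m for g, m in expr_truth.true_modules.items()}
    fpkm = pd.DataFrame(coexpr.normalize_fpkm(expr.counts, expr.gene_length_bp),
                        index=expr.gene_ids, columns=expr.sample_ids)
    de = coexpr.de_test(expr)
    de_genes = sorted(de.loc[de["direction"] != "ns", "gene_id"])
    log_expr = np.log2(fpkm + 1.0)
    filtered = coexpr.mad_filter(log_expr, 0.30)
    assignment = coexpr.build_network_modules(filtered,
                                              min_module_size=cfg["min_module_size"])
    mstats = coexpr.module_trait_stats(filtered, assignment.modules,
                                       expr.trait_values)
    hubs = coexpr.hub_genes(mstats)
    hub_list = sorted({g for lst in hubs.values() for g in lst})
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)
    assignment.modules.rename("module").to_csv(out / "modules.tsv", sep="\t")
    mstats.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    mstats.module_trait_r.to_csv(out / "module_trait_r.tsv", sep="\t")
    pd.Series({m: ",".join(g) for m, g in hubs.items()}, name="hub_genes"
              ).to_csv(out / "hub_genes.tsv", sep="\t")

    # --- integration
    overlap = overlap_candidates({
        "gwas_candidates": gwas_genes,
        "sweep_genes": sweep_genes,
        "module_hubs": hub_list,
        "de_genes": de_genes,
    })

    summary = {
        "seed": master,
        "n_accessions": geno.n_accessions,
        "n_snps_raw": geno_raw.n_sites,
        "n_snps_filtered": geno.n_sites,
        "n_windows": int(len(fst)),
        "n_sweep_intervals": int(len(intervals)),
        "genome_fraction_flagged": genome_fraction,
        "n_sweep_genes": len(sweep_genes),
        "me": thr.me,
        "p_threshold": thr.p_threshold,
        "n_significant_snps": int(sig_unique.shape[0]),
        "n_candidate_genes": len(gwas_genes),
        "n_de_genes": len(de_genes),
        "n_modules": int(len(assignment.module_sizes)),
        "n_hub_genes": len(hub_list),
        "mean_D_by_type": {k: round(v, 6) for k, v in
                           groups["groups"].set_index("group")["mean_D"].items()},
        "overlaps": {k: v["count"] for k, v in overlap["pairs"].items()},
        "triple_overlaps": {k: v["count"] for k, v in overlap["triples"].items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
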