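"""Comparing the transcriptome and translatome networks.

Four complementary views: (1) cross-tabulation of the two module
partitions with two-tailed Fisher exact tests; (2) module preservation
of the reference (RNA) modules in the test (Ribo) network via density
and connectivity statistics calibrated by size-matched permutation
(Z_summary > 10 strong, 5-10 moderate); (3) per-gene differential
intramodular connectivity DC = log10(k_in_RNA / k_in_Ribo); and (4) the
dynamic-neighborhoods score Dn — the summed squared Euclidean distance
of a gene's thresholded consensus-TO neighborhood vectors from their
centroid across the two network states — with genes more than 2 sd above
the mean flagged as rewired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import log
from .modules import BACKGROUND, ModulePartition, module_eigengene
from .network import TOMatrix, bicor_matrix, signed_adjacency

__all__ = [
    "module_overlap",
    "preservation_stats",
    "differential_connectivity",
    "dn_score",
    "rank_set_enrichment",
    "export_graphml",
]

DENSITY_STATS = ("mean_cor", "mean_adj", "prop_var_explained", "mean_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")


def module_overlap(
    partition_rna: ModulePartition,
    partition_ribo: ModulePartition,
    alpha: float = 0.01,
    include_background: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate the two partitions with Fisher exact tests.

    For every (RNA module, Ribo module) pair a 2x2 in/out table over the
    shared gene universe is tested two-tailed; pairs with p < alpha are
    flagged significant.
    """
    a = partition_rna.assignment
    b = partition_ribo.assignment.reindex(a.index)
    if b.isna().any():
        raise ValueError("partitions must cover the same gene universe")
    n = len(a)
    labels_a = partition_rna.labels + ([BACKGROUND] if include_background else [])
    labels_b = partition_ribo.labels + ([BACKGROUND] if include_background else [])
    rows = []
    for la in labels_a:
        in_a = a == la
        for lb in labels_b:
            in_b = b == lb
            k = int((in_a & in_b).sum())
            table = [[k, int(in_a.sum()) - k], [int(in_b.sum()) - k, n - int(in_a.sum()) - int(in_b.sum()) + k]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append({"rna_module": la, "ribo_module": lb, "count": k,
                         "size_rna": int(in_a.sum()), "size_ribo": int(in_b.sum()),
                         "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def _module_stats(expr_test, cor_test, adj_test, kim_ref, kme_ref, cor_ref_block, genes_idx, genes):
    """Density + connectivity statistics of one (possibly permuted) module."""
    sub_cor = cor_test[np.ix_(genes_idx, genes_idx)]
    sub_adj = adj_test[np.ix_(genes_idx, genes_idx)]
    m = len(genes_idx)
    off = ~np.eye(m, dtype=bool)
    eg, ve = module_eigengene(expr_test, genes)
    X = expr_test.loc[genes].to_numpy(dtype=float)
    kme = np.array([np.corrcoef(x, eg.to_numpy())[0, 1] if np.ptp(x) > 0 else 0.0 for x in X])
    kim_test = sub_adj[off].reshape(m, m - 1).sum(axis=1)

    def safe_cor(u, v):
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    iu = np.triu_indices(m, k=1)
    return {
        "mean_cor": float(sub_cor[off].mean()),
        "mean_adj": float(sub_adj[off].mean()),
        "prop_var_explained": float(ve),
        "mean_kme": float(np.abs(kme).mean()),
        "cor_kim": safe_cor(kim_ref, kim_test),
        "cor_kme": safe_cor(np.abs(kme_ref), np.abs(kme)),
        "cor_cor": safe_cor(cor_ref_block[iu], sub_cor[iu]),
    }


def preservation_stats(
    expr_rna: pd.DataFrame,
    expr_ribo: pd.DataFrame,
    partition_rna: ModulePartition,
    beta: float = 18.0,
    n_perm: int = 100,
    seed: int = 0,
    min_module_size: int = 4,
) -> pd.DataFrame:
    """Module preservation of reference modules in the test network.

    Density statistics (mean within-module correlation and adjacency,
    eigengene variance explained, mean |kME|) and connectivity
    statistics (cross-network correlation of intramodular connectivity,
    of kME vectors, and of vectorized within-module correlation
    matrices) are computed per reference module in the test network; a
    permutation null draws size-matched random gene sets in the test
    network. Z per statistic = (obs - perm mean)/perm sd; Z_density and
    Z_connectivity are medians of their component Zs, Z_summary their
    mean; medianRank is the mean over statistics of the module's rank
    (1 = most preserved). Classification: strong if Z_summary > 10,
    moderate if 5 < Z_summary <= 10, else not preserved.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    genes = [g for g in expr_rna.index if g in set(expr_ribo.index)]
    expr_rna = expr_rna.loc[genes]
    expr_ribo = expr_ribo.loc[genes]
    cor_rna = bicor_matrix(expr_rna.to_numpy())
    cor_ribo = bicor_matrix(expr_ribo.to_numpy())
    adj_rna = signed_adjacency(cor_rna, beta)
    adj_ribo = signed_adjacency(cor_ribo, beta)
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    all_stats = DENSITY_STATS + CONNECTIVITY_STATS
    obs_rows, z_rows, perm_meta = {}, {}, {}
    for m in partition_rna.labels:
        mem = [g for g in partition_rna.genes_of(m) if g in index_of]
        if len(mem) < min_module_size:
            warnings.warn(f"module {m} smaller than {min_module_size}; preservation skipped")
            continue
        idx = np.array([index_of[g] for g in mem])
        size = len(idx)
        off = ~np.eye(size, dtype=bool)
        # reference-side quantities for connectivity statistics
        kim_ref = adj_rna[np.ix_(idx, idx)][off].reshape(size, size - 1).sum(axis=1)
        eg_ref, _ = module_eigengene(expr_rna, mem)
        Xr = expr_rna.loc[mem].to_numpy(dtype=float)
        kme_ref = np.array([np.corrcoef(x, eg_ref.to_numpy())[0, 1] if np.ptp(x) > 0 else 0.0 for x in Xr])
        cor_ref_block = cor_rna[np.ix_(idx, idx)]

        obs = _module_stats(expr_ribo, cor_ribo, adj_ribo, kim_ref, kme_ref, cor_ref_block, idx, mem)
        perm = {s: np.empty(n_perm) for s in all_stats}
        for p in range(n_perm):
            pick = rng.choice(len(genes), size=size, replace=False)
            pgenes = [genes[i] for i in pick]
            st = _module_stats(expr_ribo, cor_ribo, adj_ribo, kim_ref, kme_ref, cor_ref_block, pick, pgenes)
            for s in all_stats:
                perm[s][p] = st[s]
        zs = {}
        for s in all_stats:
            sd = perm[s].std(ddof=1)
            zs[s] = (obs[s] - perm[s].mean()) / sd if sd > 0 else 0.0
        obs_rows[m] = obs
        z_rows[m] = zs
        perm_meta[m] = {f"perm_mean_{s}": perm[s].mean() for s in all_stats} | {
            f"perm_sd_{s}": perm[s].std(ddof=1) for s in all_stats
        }

    if not obs_rows:
        return pd.DataFrame()
    obs_df = pd.DataFrame(obs_rows).T
    z_df = pd.DataFrame(z_rows).T
    # ranks: 1 = most preserved (highest observed statistic)
    ranks = obs_df.rank(ascending=False, method="average")
    out = pd.DataFrame(index=obs_df.index)
    out["Z_density"] = z_df[list(DENSITY_STATS)].median(axis=1)
    out["Z_connectivity"] = z_df[list(CONNECTIVITY_STATS)].median(axis=1)
    out["Z_summary"] = (out["Z_density"] + out["Z_connectivity"]) / 2.0
    out["medianRank"] = ranks.mean(axis=1)
    out["class"] = np.where(out["Z_summary"] > 10, "strong",
                            np.where(out["Z_summary"] > 5, "moderate", "not_preserved"))
    for s in all_stats:
        out[f"obs_{s}"] = obs_df[s]
        out[f"Z_{s}"] = z_df[s]
    meta = pd.DataFrame(perm_meta).T
    return out.join(meta)


def differential_connectivity(
    conn_rna: pd.DataFrame,
    conn_ribo: pd.DataFrame,
    floor: float = 1e-6,
) -> pd.DataFrame:
    """DC = log10(k_in_RNA / k_in_Ribo) per gene with a 2-sd flag.

    Genes with either connectivity at or below `floor` get a missing DC
    (the log ratio is unstable there); the flag marks genes whose DC
    exceeds the mean by more than two standard deviations over the
    non-missing genes.
    """
    genes = [g for g in conn_rna.index if g in set(conn_ribo.index)]
    k_rna = conn_rna.loc[genes, "k_in"].to_numpy(dtype=float)
    k_ribo = conn_ribo.loc[genes, "k_in"].to_numpy(dtype=float)
    dc = np.full(len(genes), np.nan)
    ok = (k_rna > floor) & (k_ribo > floor)
    dc[ok] = np.log10(k_rna[ok] / k_ribo[ok])
    out = pd.DataFrame({"k_in_rna": k_rna, "k_in_ribo": k_ribo, "dc": dc}, index=genes)
    valid = out["dc"].dropna()
    if len(valid) >= 2:
        cut = valid.mean() + 2.0 * valid.std(ddof=1)
        out["dc_flag"] = out["dc"] > cut
    else:
        out["dc_flag"] = False
    out["dc_flag"] = out["dc_flag"].fillna(False).astype(bool)
    return out


def dn_score(
    cons_tom_rna: TOMatrix,
    cons_tom_ribo: TOMatrix,
    edge_threshold: float = 0.1,
) -> pd.DataFrame:
    """Dynamic-neighborhoods score per gene across the two network states.

    Both consensus TOMs are thresholded (entries below `edge_threshold`
    set to 0, diagonal excluded); a gene's state vectors V_RNA, V_Ribo
    are its thresholded neighborhood weights over all other genes, and
    Dn = d(V_RNA, c)^2 + d(V_Ribo, c)^2 with c their centroid — equal to
    ||V_RNA - V_Ribo||^2 / 2. Genes more than 2 sd above the mean Dn are
    flagged rewired; genes with empty neighborhoods in both states get
    Dn = 0 and an isolated flag.
    """
    ga, gb = list(cons_tom_rna.gene_ids), list(cons_tom_ribo.gene_ids)
    if ga and gb and ga != gb:
        common = [g for g in ga if g in set(gb)]
        ia = [ga.index(g) for g in common]
        ib = [gb.index(g) for g in common]
        Tr = cons_tom_rna.values[np.ix_(ia, ia)]
        Tb = cons_tom_ribo.values[np.ix_(ib, ib)]
        genes = common
    else:
        Tr, Tb = cons_tom_rna.values, cons_tom_ribo.values
        genes = ga or list(range(Tr.shape[0]))
    if Tr.shape != Tb.shape:
        raise ValueError("gene sets of the two TOMs do not match")

    Vr = np.where(Tr >= edge_threshold, Tr, 0.0).astype(float)
    Vb = np.where(Tb >= edge_threshold, Tb, 0.0).astype(float)
    np.fill_diagonal(Vr, 0.0)
    np.fill_diagonal(Vb, 0.0)
    centroid = (Vr + Vb) / 2.0
    dn = ((Vr - centroid) ** 2).sum(axis=1) + ((Vb - centroid) ** 2).sum(axis=1)
    n_rna = (Vr > 0).sum(axis=1)
    n_ribo = (Vb > 0).sum(axis=1)
    out = pd.DataFrame({"dn": dn, "n_neighbors_rna": n_rna, "n_neighbors_ribo": n_ribo},
                       index=genes)
    out["isolated"] = (n_rna == 0) & (n_ribo == 0)
    cut = dn.mean() + 2.0 * dn.std(ddof=1)
    out["dn_flag"] = (dn > cut) & ~out["isolated"]
    return out


def rank_set_enrichment(dn: pd.Series, gene_sets: dict) -> pd.DataFrame:
    """One-sided rank-sum enrichment of gene sets in the Dn ranking.

    For each set, a Wilcoxon rank-sum test (normal approximation with
    tie correction) of the set's Dn scores against the complement,
    alternative: set scores are higher. A rank export suitable for
    barcode plots is available via the returned `rank` column order.
    Empty sets are skipped; a set covering all genes is an error.
    """
    scores = dn.dropna()
    rows = []
    for name, members in gene_sets.items():
        members = [g for g in members if g in scores.index]
        if not members:
            warnings.warn(f"gene set {name} is empty after intersection; skipped")
            continue
        if len(members) == len(scores):
            raise ValueError(f"gene set {name} covers all scored genes; no complement")
        in_set = scores.loc[members]
        out_set = scores.drop(members)
        stat, p = stats.mannwhitneyu(in_set, out_set, alternative="greater", method="asymptotic")
        rows.append({"set": name, "n_set": len(in_set), "n_background": len(out_set),
                     "statistic": float(stat), "p": float(p), "method": "wilcoxon_rank_sum"})
    return pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame()


def export_graphml(tom: TOMatrix, path: str, cutoff: float = 0.1) -> None:
    """Write the thresholded network as GraphML (weight-annotated edges)."""
    import networkx as nx

    g = nx.Graph()
    ids = tom.gene_ids or list(range(tom.n_genes))
    g.add_nodes_from(ids)
    edges = tom.edge_list(cutoff)
    for _, row in edges.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], weight=float(row["weight"]))
    nx.write_graphml(g, path)
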