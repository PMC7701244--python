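"""Module/gene to phenotype association.

Binary group contrasts (pathological vs physiological, and per-timepoint
TAC vs swim) are coded 0/1, with contrast-irrelevant samples marked
missing and excluded pairwise. Continuous-continuous correlation uses
the biweight midcorrelation; any correlation involving a binary trait
uses Pearson. p-values come from the Student t transform of the
correlation. Module membership (kME) is the bicor of a gene with a
module eigengene; gene significance (GS) is its correlation with a
trait; representative gene sets join a module's hubs with the genes in
the upper quartile of both |kME| and |GS| for the module's best trait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import log
from .modules import ModulePartition
from .network import bicor

__all__ = [
    "TraitTable",
    "binarize_traits",
    "correlate",
    "module_trait_matrix",
    "module_membership",
    "gene_significance",
    "select_representative_genes",
    "order_modules_by_trait",
]

CONTRASTS = ("pathological_vs_physiological", "tac2d_vs_swim2d", "tac2w_vs_swim2w")


@dataclass
class TraitTable:
    """sample x trait values; binary contrasts are 0/1 with NaN = not applicable."""

    values: pd.DataFrame
    is_binary: dict

    def __post_init__(self):
        for t, flag in self.is_binary.items():
            if flag:
                seen = set(self.values[t].dropna().unique())
                if not seen <= {0.0, 1.0}:
                    raise ValueError(f"binary trait {t} must be coded 0/1")


def binarize_traits(metadata: pd.DataFrame) -> TraitTable:
    """Build the trait table from sample metadata.

    metadata needs columns `group` (swim/tac) and `timepoint` (2d/2w),
    indexed by sample; an optional `hwbw` column passes through as a
    continuous trait. Contrast coding: 1 = pathological (TAC).
    Degenerate (constant) traits are flagged and excluded downstream.
    """
    group = metadata["group"].astype(str).str.lower()
    timepoint = metadata["timepoint"].astype(str).str.lower()
    bad = set(group.unique()) - {"swim", "tac"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    vals = pd.DataFrame(index=metadata.index)
    vals["pathological_vs_physiological"] = (group == "tac").astype(float)
    for tp, name in (("2d", "tac2d_vs_swim2d"), ("2w", "tac2w_vs_swim2w")):
        col = pd.Series(np.nan, index=metadata.index)
        sel = timepoint == tp
        col[sel] = (group[sel] == "tac").astype(float)
        vals[name] = col
    is_binary = {c: True for c in vals.columns}
    if "hwbw" in metadata.columns:
        vals["hwbw"] = metadata["hwbw"].astype(float)
        is_binary["hwbw"] = False
    for c in list(vals.columns):
        if vals[c].dropna().nunique() < 2:
            warnings.warn(f"trait {c} is degenerate; excluded")
            vals = vals.drop(columns=c)
            del is_binary[c]
    return TraitTable(values=vals, is_binary=is_binary)


def correlate(x, y, binary: bool = False) -> tuple[float, float]:
    """Correlation plus two-sided Student p.

    bicor for continuous pairs, Pearson when either variable is binary.
    Pairs with a missing value are excluded; fewer than 3 complete pairs
    is an error. Constant vectors return (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    if binary:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = bicor(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return (r, float(np.finfo(float).tiny))
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return (r, max(p, float(np.finfo(float).tiny)))


def module_trait_matrix(
    eigengenes: pd.DataFrame, traits: TraitTable
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correlate each eigengene with each trait.

    Returns (cor, p, p_bh); the BH column-stacked adjustment is reported
    alongside the raw Student p-values for transparency.
    """
    samples = eigengenes.columns
    tv = traits.values.reindex(samples)
    cor = pd.DataFrame(index=eigengenes.index, columns=tv.columns, dtype=float)
    p = cor.copy()
    for m in eigengenes.index:
        for t in tv.columns:
            r, pv = correlate(eigengenes.loc[m], tv[t], binary=traits.is_binary[t])
            cor.loc[m, t], p.loc[m, t] = r, pv
    flat = p.to_numpy().ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    p_bh = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return cor, p, p_bh


def module_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: bicor of every gene with every module eigengene."""
    out = pd.DataFrame(index=expr.index, columns=eigengenes.index, dtype=float)
    X = expr.to_numpy(dtype=float)
    for m in eigengenes.index:
        eg = eigengenes.loc[m].to_numpy(dtype=float)
        for i, g in enumerate(expr.index):
            if np.ptp(X[i]) == 0:
                out.loc[g, m] = np.nan
            else:
                out.loc[g, m] = bicor(X[i], eg)
    return out


def gene_significance(expr: pd.DataFrame, traits: TraitTable) -> pd.DataFrame:
    """GS: correlation of every gene with every trait (binary rule applies)."""
    out = pd.DataFrame(index=expr.index, columns=traits.values.columns, dtype=float)
    tv = traits.values.reindex(expr.columns)
    for t in tv.columns:
        y = tv[t].to_numpy(dtype=float)
        for g in expr.index:
            x = expr.loc[g].to_numpy(dtype=float)
            if np.ptp(x[~np.isnan(y)]) == 0:
                out.loc[g, t] = np.nan
                continue
            r, _ = correlate(x, y, binary=traits.is_binary[t])
            out.loc[g, t] = r
    return out


def select_representative_genes(
    kme: pd.DataFrame,
    gs: pd.DataFrame,
    partition: ModulePartition,
    hubs: pd.DataFrame | None = None,
) -> dict:
    """Representative gene set per module: hubs plus double upper quartile.

    For each module, the trait maximizing the correlation between |kME|
    (own module) and |GS| across the module's genes is chosen (ties by
    fixed trait column order); the set is the module's hub genes union
    the genes in the upper quartile of both |kME| and |GS| for that
    trait. Modules with fewer than 4 genes contribute hubs only.
    """
    result = {}
    for m in partition.labels:
        genes = partition.genes_of(m)
        hub_set = set()
        if hubs is not None:
            sub = hubs.loc[[g for g in genes if g in hubs.index]]
            hub_set = set(sub.index[sub["is_hub"]])
        if len(genes) < 4:
            warnings.warn(f"module {m} smaller than 4 genes; hubs only")
            result[m] = {"trait": None, "genes": sorted(hub_set)}
            continue
        akme = kme.loc[genes, m].abs()
        best_trait, best_cor = None, -np.inf
        for t in gs.columns:
            ags = gs.loc[genes, t].abs()
            ok = ~(akme.isna() | ags.isna())
            if ok.sum() < 3:
                continue
            c = np.corrcoef(akme[ok], ags[ok])[0, 1]
            if np.isnan(c):
                c = -np.inf
            if c > best_cor:
                best_trait, best_cor = t, c
        if best_trait is None:
            best_trait = gs.columns[0]
            log.info("module %s: no informative trait, fixed-order tie-break -> %s", m, best_trait)
        ags = gs.loc[genes, best_trait].abs()
        q_kme = akme.quantile(0.75)
        q_gs = ags.quantile(0.75)
        upper = [g for g in genes if akme[g] >= q_kme and ags[g] >= q_gs]
        result[m] = {"trait": best_trait, "genes": sorted(hub_set | set(upper))}
    return result


def order_modules_by_trait(
    module_trait_cor: pd.DataFrame,
    anchor_trait: str = "pathological_vs_physiological",
    prefix: str = "M",
) -> dict:
    """Relabel modules by the leaf order of clustering their trait profiles.

    Modules are hierarchically clustered (average linkage, correlation
    distance on module-trait correlation vectors) and numbered along the
    dendrogram leaves, anchored so that the module most positively
    correlated with the pathological contrast gets label <prefix>1.
    Returns old-label -> new-label mapping.
    """
    C = module_trait_cor.fillna(0.0)
    labels = list(C.index)
    if len(labels) == 1:
        return {labels[0]: f"{prefix}1"}
    V = C.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        D = 1.0 - np.corrcoef(V) if V.shape[1] > 1 else np.abs(V - V.T)
    D = np.nan_to_num(D, nan=2.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    from scipy.spatial.distance import squareform

    order = leaves_list(linkage(squareform(D, checks=False), method="average"))
    leaf_labels = [labels[i] for i in order]
    if anchor_trait in C.columns:
        anchor_vals = C[anchor_trait]
        top = anchor_vals.idxmax()
        if leaf_labels.index(top) > len(leaf_labels) / 2:
            leaf_labels = leaf_labels[::-1]
    return {old: f"{prefix}{i + 1}" for i, old in enumerate(leaf_labels)}
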