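"""From raw counts to the expression matrix that feeds both networks.

Fixed order: sequencing-depth normalization (median-of-ratios size
factors) -> removal of bottom-centile mean-expression and low-variance
genes -> regularized log transform (shifted log2 of depth-normalized
counts) -> empirical-Bayes batch correction -> selection of the genes
with the highest whole-network soft connectivity. Both assays leave the
pipeline with the identical ordered gene list, so the two networks are
built on a common gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._utils import log
from .network import bicor_matrix, signed_adjacency

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "size_factors",
    "filter_genes",
    "rlog_transform",
    "batch_correct",
    "select_by_connectivity",
    "preprocess_pair",
]


@dataclass
class CountMatrix:
    """Integer gene x sample counts for one assay (RNA or Ribo)."""

    values: pd.DataFrame
    assay: str = "RNA"

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("duplicate gene or sample IDs")
        arr = df.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.values = df.astype(np.int64, copy=False) if not np.issubdtype(arr.dtype, np.integer) else df

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Transformed gene x sample values on the scale fed to correlation."""

    values: pd.DataFrame
    assay: str = "RNA"
    transform_tag: str = ""

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference is the per-gene geometric mean over genes nonzero in
    all samples; each sample's factor is the median of its count/reference
    ratios, normalized to geometric mean 1. If no gene is nonzero in all
    samples, falls back to total-count scaling with a warning.
    """
    df = counts.values
    arr = df.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        warnings.warn("no gene nonzero in all samples; using total-count scaling")
        factors = arr.sum(axis=0)
    else:
        sub = arr[allpos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _normalized_means(counts: CountMatrix) -> pd.Series:
    f = size_factors(counts)
    return (counts.values / f).mean(axis=1)


def filter_genes(
    counts_rna: CountMatrix,
    counts_ribo: CountMatrix,
    variance_floor: float = 0.0,
    centile: float = 0.01,
    pseudocount: float = 1.0,
) -> list:
    """Genes surviving the bottom-centile mean and low-variance filters.

    Per assay, genes whose depth-normalized mean expression falls in the
    bottom `centile` are removed (union of the two assays' removals), as
    are genes whose log-scale variance is <= variance_floor in either
    assay. Survivors are returned in input order.
    """
    if list(counts_rna.values.index) != list(counts_ribo.values.index):
        raise ValueError("assays must share an identical ordered gene set")
    genes = counts_rna.values.index
    drop = pd.Series(False, index=genes)
    for cm in (counts_rna, counts_ribo):
        means = _normalized_means(cm)
        n_drop = int(np.ceil(centile * len(genes)))
        if n_drop > 0:
            # ties at the cutoff all go: rank by (mean, position) for determinism
            order = np.lexsort((np.arange(len(genes)), means.to_numpy()))
            drop.iloc[order[:n_drop]] = True
        logged = np.log2(cm.values / size_factors(cm) + pseudocount)
        drop |= logged.var(axis=1, ddof=1) <= variance_floor
    kept = [g for g in genes if not drop[g]]
    if not kept:
        raise ValueError("all genes removed by filtering")
    log.info("filter_genes: %d -> %d genes", len(genes), len(kept))
    return kept


def rlog_transform(
    counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Shifted log2 of depth-normalized counts.

    values = log2(count / size_factor + pseudocount); monotone in counts
    within each sample and invariant to doubling counts and factors
    together.
    """
    vals = np.log2(counts.values / factors + pseudocount)
    return ExpressionMatrix(
        values=vals, assay=counts.assay, transform_tag=f"log2(count/sf+{pseudocount:g})"
    )


def batch_correct(expr: ExpressionMatrix, batches) -> ExpressionMatrix:
    """Per-gene location/scale empirical-Bayes batch adjustment.

    Standardizes each gene, estimates per-batch means and variances,
    shrinks them toward across-gene priors (normal prior on means,
    moment-matched inverse-gamma prior on variances), removes the batch
    effect and restores each gene's grand location/scale. A single batch
    is an exact identity transform.
    """
    df = expr.values
    batches = pd.Series(batches, index=df.columns) if not isinstance(batches, pd.Series) else batches.reindex(df.columns)
    levels = sorted(batches.unique())
    counts = batches.value_counts()
    if len(levels) == 1:
        return ExpressionMatrix(values=df.copy(), assay=expr.assay,
                                transform_tag=expr.transform_tag + "|batch:identity")
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")

    X = df.to_numpy(dtype=float)
    grand_mean = X.mean(axis=1, keepdims=True)
    grand_sd = X.std(axis=1, ddof=1, keepdims=True)
    sd_safe = np.where(grand_sd == 0, 1.0, grand_sd)
    Z = (X - grand_mean) / sd_safe

    corrected = np.empty_like(Z)
    for b in levels:
        cols = np.flatnonzero((batches == b).to_numpy())
        Zb = Z[:, cols]
        gamma_hat = Zb.mean(axis=1)                       # per-gene batch mean
        delta_hat = Zb.var(axis=1, ddof=1)                # per-gene batch variance
        # normal prior on means, moment-matched across genes
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        nb = len(cols)
        if tau2 > 0:
            gamma_star = (nb * tau2 * gamma_hat + delta_hat * gamma_bar) / (nb * tau2 + delta_hat)
        else:
            gamma_star = np.full_like(gamma_hat, gamma_bar)
        # inverse-gamma prior on variances, moment-matched
        d_bar = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        if d_var > 0:
            a_prior = (2 * d_var + d_bar**2) / d_var
            b_prior = (d_bar * d_var + d_bar**3) / d_var
            delta_star = (b_prior + 0.5 * np.sum((Zb - gamma_star[:, None]) ** 2, axis=1)) / (
                nb / 2 + a_prior - 1
            )
        else:
            delta_star = np.full_like(delta_hat, d_bar)
        delta_star = np.maximum(delta_star, 1e-12)
        corrected[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = corrected * sd_safe + grand_mean
    out = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=out, assay=expr.assay,
                            transform_tag=expr.transform_tag + "|batch:eb")


def select_by_connectivity(
    expr_rna: ExpressionMatrix,
    expr_ribo: ExpressionMatrix,
    k_keep: int,
    beta: float = 18.0,
    rank_by: str = "mean_rank",
) -> list:
    """Top-k genes by whole-network soft connectivity.

    Per assay, k_i = sum_{j != i} a_ij under the signed adjacency at
    `beta`; genes are ranked per assay (higher connectivity = better
    rank) and the combined score is the mean of the two per-assay ranks
    ("mean_rank", default), or a single assay's rank ("rna"/"ribo").
    Ties in the combined rank break by gene-ID lexicographic order.
    """
    if k_keep <= 0:
        raise ValueError("k_keep must be positive")
    if list(expr_rna.values.index) != list(expr_ribo.values.index):
        raise ValueError("assays must share an identical ordered gene set")
    genes = expr_rna.values.index
    if k_keep >= len(genes):
        return list(genes)

    def soft_k(e: ExpressionMatrix) -> np.ndarray:
        adj = signed_adjacency(bicor_matrix(e.values.to_numpy()), beta)
        return adj.sum(axis=1) - 1.0

    k_rna, k_ribo = soft_k(expr_rna), soft_k(expr_ribo)
    r_rna = rankdata(-k_rna, method="average")
    r_ribo = rankdata(-k_ribo, method="average")
    if rank_by == "mean_rank":
        score = (r_rna + r_ribo) / 2.0
    elif rank_by == "rna":
        score = r_rna
    elif rank_by == "ribo":
        score = r_ribo
    else:
        raise ValueError("rank_by must be rna, ribo or mean_rank")
    order = sorted(range(len(genes)), key=lambda i: (score[i], str(genes[i])))
    keep = set(order[:k_keep])
    return [g for i, g in enumerate(genes) if i in keep]


def preprocess_pair(
    counts_rna: CountMatrix,
    counts_ribo: CountMatrix,
    batches=None,
    variance_floor: float = 0.0,
    centile: float = 0.01,
    pseudocount: float = 1.0,
    k_keep: int | None = None,
    beta: float = 18.0,
    rank_by: str = "mean_rank",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Run the full preprocessing chain on a paired count dataset."""
    kept = filter_genes(counts_rna, counts_ribo, variance_floor, centile, pseudocount)
    out = []
    for cm in (counts_rna, counts_ribo):
        sub = CountMatrix(values=cm.values.loc[kept], assay=cm.assay)
        e = rlog_transform(sub, size_factors(sub), pseudocount)
        if batches is not None:
            e = batch_correct(e, batches)
        out.append(e)
    expr_rna, expr_ribo = out
    if k_keep is not None and k_keep < len(kept):
        top = select_by_connectivity(expr_rna, expr_ribo, k_keep, beta, rank_by)
        expr_rna = ExpressionMatrix(expr_rna.values.loc[top], expr_rna.assay, expr_rna.transform_tag)
        expr_ribo = ExpressionMatrix(expr_ribo.values.loc[top], expr_ribo.assay, expr_ribo.transform_tag)
        log.info("connectivity selection: %d -> %d genes", len(kept), len(top))
    return expr_rna, expr_ribo
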