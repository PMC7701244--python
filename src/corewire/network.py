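"""Signed weighted co-expression networks and topological overlap.

The similarity backbone is the biweight midcorrelation (bicor), a robust
correlation that downweights samples far from the median with Tukey
biweights. Signed adjacencies are a_ij = ((1 + cor_ij)/2)**beta so that
anti-correlated genes get near-zero edge weight; the topological overlap
matrix (TOM) then augments direct edges with shared-neighbor weight. A
bootstrap-consensus TOM — the elementwise median of quantile-scaled TOMs
over within-group resamples of the samples — provides the robust input for
module detection.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import log

__all__ = [
    "NetworkConfig",
    "TOMatrix",
    "bicor",
    "bicor_matrix",
    "signed_adjacency",
    "topological_overlap",
    "consensus_tom",
    "adjacency_from_expression",
    "pick_soft_threshold",
]


@dataclass
class NetworkConfig:
    """Parameters of network construction.

    beta: soft-threshold exponent of the signed adjacency (>= 1).
    n_boot: number of bootstrap resamples for the consensus TOM (>= 1).
    scale_quantile: reference quantile used to scale each bootstrap TOM
        onto the full-data reference TOM, in (0, 1).
    resample_groups: sample id -> group label; resampling is stratified
        within these groups (group sizes preserved). None = one group.
    seed: RNG seed for the bootstrap draws.
    """

    beta: float = 18.0
    n_boot: int = 100
    scale_quantile: float = 0.95
    resample_groups: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.scale_quantile < 1:
            raise ValueError("scale_quantile must be in (0, 1)")


@dataclass
class TOMatrix:
    """Symmetric topological-overlap matrix with gene labels.

    kind is "plain" (single TOM) or "consensus" (median of scaled
    bootstrap TOMs). Entries lie in [0, 1] with unit diagonal.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    kind: str = "plain"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("TOM must be square")
        if self.gene_ids and len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = self.gene_ids or list(range(self.n_genes))
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def save(self, prefix: str) -> None:
        """Persist as <prefix>.npy plus a JSON sidecar with labels/kind."""
        np.save(prefix + ".npy", self.values)
        with open(prefix + ".json", "w") as fh:
            json.dump({"gene_ids": list(self.gene_ids), "kind": self.kind}, fh)

    @classmethod
    def load(cls, prefix: str) -> "TOMatrix":
        values = np.load(prefix + ".npy")
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        return cls(values=values, gene_ids=meta["gene_ids"], kind=meta["kind"])

    def edge_list(self, cutoff: float = 0.1) -> pd.DataFrame:
        """Upper-triangle edges with weight >= cutoff, as a tidy table."""
        iu, ju = np.triu_indices(self.n_genes, k=1)
        w = self.values[iu, ju]
        keep = w >= cutoff
        ids = np.asarray(self.gene_ids or list(range(self.n_genes)))
        return pd.DataFrame(
            {"gene_a": ids[iu[keep]], "gene_b": ids[ju[keep]], "weight": w[keep]}
        )


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _bicor_weights(x: np.ndarray):
    """Return (centered*weighted vector, used Pearson fallback?) for one row."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        c = x - x.mean()
        return c, True
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1)
    return (x - med) * w, False


def bicor(x, y) -> float:
    """Biweight midcorrelation of two sample vectors.

    Falls back to Pearson centering for a vector whose median absolute
    deviation is zero (constant-majority vector), which avoids NaNs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("bicor requires at least 3 samples")
    a, fall_a = _bicor_weights(x)
    b, fall_b = _bicor_weights(y)
    if fall_a or fall_b:
        log.debug("bicor: zero MAD, Pearson fallback used")
    na = np.sqrt(np.sum(a**2))
    nb = np.sqrt(np.sum(b**2))
    if na == 0 or nb == 0:
        return np.nan
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise bicor of a gene x sample matrix, vectorized.

    Rows with zero MAD use Pearson centering; rows that are constant
    (zero norm after centering) get correlation 0 with everything else
    and 1 with themselves.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a 2-D matrix with >= 3 samples")
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1, (1.0 - u**2) ** 2, 0.0)
    A = (X - med) * w
    if zero_mad.any():
        A[zero_mad] = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", A, A))
    degenerate = norms == 0
    norms[degenerate] = 1.0
    A = A / norms[:, None]
    C = A @ A.T
    np.clip(C, -1.0, 1.0, out=C)
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


# ---------------------------------------------------------------------------
# adjacency and topological overlap


def signed_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)**beta.

    Negative correlation maps toward zero weight; the diagonal is set
    to 1 regardless of beta.
    """
    cor = np.asarray(cor, dtype=float)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adj: np.ndarray, gene_ids=None) -> TOMatrix:
    """Topological overlap of a signed adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i the (off-diagonal) node
    connectivity; the diagonal is 1.
    """
    adj = np.asarray(adj, dtype=float)
    A = adj.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return TOMatrix(values=tom, gene_ids=list(gene_ids) if gene_ids is not None else [], kind="plain")


def adjacency_from_expression(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """bicor -> signed adjacency straight from a gene x sample frame."""
    return signed_adjacency(bicor_matrix(expr.to_numpy()), beta)


# ---------------------------------------------------------------------------
# bootstrap consensus TOM


def _group_indices(sample_ids, resample_groups):
    if resample_groups is None:
        return [np.arange(len(sample_ids))]
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        groups.setdefault(str(resample_groups[s]), []).append(i)
    return [np.asarray(v) for _, v in sorted(groups.items())]


def consensus_tom(
    expr: pd.DataFrame,
    config: NetworkConfig,
    *,
    identity_draw: bool = False,
) -> TOMatrix:
    """Bootstrap-consensus topological overlap matrix.

    A reference TOM is computed on the full expression matrix. For each
    of n_boot iterations, samples are redrawn with replacement
    independently within each resample group (group sizes preserved),
    the TOM is recomputed and scaled so that its scale_quantile-th
    off-diagonal quantile matches the reference TOM's, and the consensus
    is the elementwise median of the scaled TOMs, clipped to [0, 1].

    Bootstrap TOMs are streamed through an on-disk float32 buffer, so
    peak memory stays O(n_genes^2) rather than O(n_genes^2 * n_boot).

    identity_draw replaces every resample by the identity permutation
    (a test hook: with n_boot=1 the consensus equals the reference TOM).
    """
    X = expr.to_numpy(dtype=float)
    gene_ids = list(expr.index)
    n_genes, n_samples = X.shape
    idx_groups = _group_indices(list(expr.columns), config.resample_groups)
    for g in idx_groups:
        if len(g) < 3:
            raise ValueError("every resample group needs >= 3 samples")

    ref = topological_overlap(signed_adjacency(bicor_matrix(X), config.beta)).values
    iu, ju = np.triu_indices(n_genes, k=1)
    q_ref = np.quantile(ref[iu, ju], config.scale_quantile)
    if q_ref == 0:
        warnings.warn("reference TOM quantile is zero; bootstrap scaling skipped")

    rng = np.random.default_rng(config.seed)
    n_pairs = iu.size
    with tempfile.TemporaryDirectory(prefix="corewire_tom_") as tmp:
        buf_path = os.path.join(tmp, "boot_toms.f32")
        buf = np.memmap(buf_path, dtype=np.float32, mode="w+", shape=(config.n_boot, n_pairs))
        for b in range(config.n_boot):
            if identity_draw:
                take = np.arange(n_samples)
            else:
                take = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in idx_groups])
            tom_b = topological_overlap(
                signed_adjacency(bicor_matrix(X[:, take]), config.beta)
            ).values[iu, ju]
            if q_ref > 0:
                q_b = np.quantile(tom_b, config.scale_quantile)
                if q_b > 0:
                    tom_b = tom_b * (q_ref / q_b)
            buf[b] = tom_b.astype(np.float32)
        buf.flush()
        # median over bootstraps, in column chunks to bound memory
        med = np.empty(n_pairs, dtype=float)
        chunk = max(1, int(5e7 // max(config.n_boot, 1)))
        for start in range(0, n_pairs, chunk):
            stop = min(start + chunk, n_pairs)
            med[start:stop] = np.median(np.asarray(buf[:, start:stop], dtype=float), axis=0)
        del buf

    cons = np.eye(n_genes)
    cons[iu, ju] = med
    cons[ju, iu] = med
    np.clip(cons, 0.0, 1.0, out=cons)
    np.fill_diagonal(cons, 1.0)
    return TOMatrix(values=cons, gene_ids=gene_ids, kind="consensus")


# ---------------------------------------------------------------------------
# soft-threshold diagnostic


def pick_soft_threshold(
    expr: pd.DataFrame,
    betas=(1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology diagnostic over a grid of soft thresholds.

    For each beta, computes the whole-network soft connectivities, bins
    them, and fits log10 p(k) ~ log10 k; reports the fit R^2 (with the
    sign of the slope) plus mean/median/max connectivity. Diagnostic
    only — the pipeline never auto-selects beta from it.
    """
    cor = bicor_matrix(expr.to_numpy())
    rows = []
    for beta in betas:
        adj = signed_adjacency(cor, beta)
        k = adj.sum(axis=1) - 1.0
        pos = k[k > 0]
        if pos.size < n_bins:
            rows.append({"beta": beta, "sft_r2": np.nan, "slope": np.nan,
                         "mean_k": k.mean(), "median_k": np.median(k), "max_k": k.max()})
            continue
        edges = np.quantile(pos, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        which = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, len(edges) - 2)
        centers, freqs = [], []
        for b in range(len(edges) - 1):
            members = pos[which == b]
            if members.size:
                centers.append(members.mean())
                freqs.append(members.size / pos.size)
        x = np.log10(np.asarray(centers))
        y = np.log10(np.asarray(freqs))
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
        rows.append({"beta": beta, "sft_r2": -np.sign(slope) * r2, "slope": slope,
                     "mean_k": k.mean(), "median_k": np.median(k), "max_k": k.max()})
    return pd.DataFrame(rows).set_index("beta")
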