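"""Module detection on the consensus TOM and module-level statistics.

Genes are clustered by average-linkage hierarchical clustering of the
dissimilarity 1 - TOM; branches are cut at a height controlled by
`deep_split`, undersized clusters fall to background, and a hybrid
reassignment stage re-admits background genes that are as topologically
close to a module as its own typical member. Modules with highly
correlated eigengenes are merged to a fixed point. Each module is
validated against size-matched random gene sets with a one-proportion
Z-test on mean topological overlap, and hub genes are flagged by their
intramodular-connectivity Z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from ._utils import log
from .network import TOMatrix

__all__ = [
    "BACKGROUND",
    "ModulePartition",
    "ModuleValidation",
    "cluster_modules",
    "module_eigengene",
    "eigengene_matrix",
    "merge_modules",
    "refine_by_kme",
    "filter_noise_modules",
    "validate_modules",
    "intramodular_connectivity",
    "find_hub_genes",
]

BACKGROUND = "background"


@dataclass
class ModulePartition:
    """gene -> module label map (the background label is allowed)."""

    assignment: pd.Series
    module_order: list = field(default_factory=list)

    def __post_init__(self):
        self.assignment = self.assignment.astype(str)
        if not self.module_order:
            self.module_order = self.labels

    @property
    def labels(self) -> list:
        return sorted(l for l in self.assignment.unique() if l != BACKGROUND)

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts()

    def genes_of(self, label: str) -> list:
        return list(self.assignment.index[self.assignment == label])

    def relabel(self, mapping: dict) -> "ModulePartition":
        new = self.assignment.map(lambda l: mapping.get(l, l))
        order = [mapping.get(l, l) for l in self.module_order]
        return ModulePartition(assignment=new, module_order=order)


@dataclass
class ModuleValidation:
    """Per-module resampling validation of mean topological overlap."""

    table: pd.DataFrame  # module x {mean_to_observed, n_resamples, n_random_higher, p_hat, z, p}


def _attachment(tom: np.ndarray, labels: np.ndarray, modules) -> tuple[dict, dict]:
    """Mean TO of every gene to each module, plus per-module thresholds.

    The threshold of a module is `attach_frac` of the median member
    attachment; with a soft-threshold power of 18 member attachments
    span orders of magnitude, so the fraction must be permissive.
    """
    offdiag = tom.copy()
    np.fill_diagonal(offdiag, 0.0)
    mean_to, median_member = {}, {}
    for m in modules:
        idx = np.flatnonzero(labels == m)
        to_mod = offdiag[:, idx].sum(axis=1)
        to_mod[idx] /= max(len(idx) - 1, 1)
        others = np.setdiff1d(np.arange(len(labels)), idx)
        to_mod[others] /= max(len(idx), 1)
        mean_to[m] = to_mod
        median_member[m] = np.median(to_mod[idx])
    return mean_to, median_member


def _prune_and_admit(tom: np.ndarray, labels: np.ndarray, attach_frac: float,
                     min_module_size: int, admit: bool = True) -> np.ndarray:
    """Drop weakly attached members, then re-admit background genes.

    A member whose mean TO to its own module falls below attach_frac of
    the module's median member attachment is sent to background (prunes
    chained-in stray genes); a background gene joins its best module if
    it clears the same bar — the topological analogue of the PAM stage
    of hybrid tree cutting. Modules shrinking below min_module_size
    dissolve.
    """
    out = labels.copy()
    modules = [int(u) for u in np.unique(out) if u != -1]
    if not modules:
        return out
    mean_to, med = _attachment(tom, out, modules)
    for m in modules:
        thr = attach_frac * med[m]
        idx = np.flatnonzero(out == m)
        weak = idx[mean_to[m][idx] < thr]
        out[weak] = -1
        if (out == m).sum() < min_module_size:
            out[out == m] = -1
    modules = [m for m in modules if (out == m).any()]
    if not modules or not admit:
        return out
    mean_to, med = _attachment(tom, out, modules)
    for i in np.flatnonzero(out == -1):
        best = max(modules, key=lambda m: mean_to[m][i])
        v = mean_to[best][i]
        if v >= attach_frac * med[best] and v > 0:
            out[i] = best
    return out


# deep_split 0..4 -> split-eagerness multiplier on the modularity null
_SPLIT_BIAS = (0.5, 1.0, 2.0, 4.0, 8.0)


def _modular_tree_cut(Z: np.ndarray, tom: np.ndarray, min_module_size: int,
                      deep_split: int = 2) -> np.ndarray:
    """Branch-adaptive cut of the dendrogram guided by TOM modularity.

    Walks the tree top-down. Side branches smaller than min_module_size
    are trimmed to background (stray genes chained near the root peel
    off naturally). A branch whose two children are both large enough is
    split when the cross-branch TOM weight falls below the weighted-
    modularity null k_L * k_R / 2m (node strengths k, total weight 2m)
    scaled by the deep_split bias — i.e. when splitting increases
    modularity; otherwise the branch is a final module. Returns labels
    (-1 = background), deterministic.
    """
    from scipy.cluster.hierarchy import to_tree

    n = tom.shape[0]
    W = tom.copy()
    np.fill_diagonal(W, 0.0)
    strength = W.sum(axis=1)
    two_m = strength.sum()
    bias = _SPLIT_BIAS[int(np.clip(deep_split, 0, 4))]
    labels = np.full(n, -1, dtype=int)
    if two_m <= 0:
        return labels
    root = to_tree(Z)
    next_label = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.count < min_module_size:
            continue  # leaves stay background
        if node.is_leaf():
            continue
        left, right = node.left, node.right
        if left.count < min_module_size and right.count < min_module_size:
            labels[node.pre_order(lambda l: l.id)] = next_label
            next_label += 1
            continue
        if left.count < min_module_size or right.count < min_module_size:
            # trim the stray side branch, keep descending the big one
            stack.append(left if left.count >= min_module_size else right)
            continue
        li = np.asarray(left.pre_order(lambda l: l.id))
        ri = np.asarray(right.pre_order(lambda l: l.id))
        cross = W[np.ix_(li, ri)].sum()
        null = strength[li].sum() * strength[ri].sum() / two_m
        if cross < bias * null:
            stack.append(left)
            stack.append(right)
        else:
            ids = np.concatenate([li, ri])
            labels[ids] = next_label
            next_label += 1
    return labels


def cluster_modules(
    cons_tom: TOMatrix,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
    hybrid: bool = True,
    cohesion: float = 2.0,
    attach_frac: float = 0.2,
) -> ModulePartition:
    """Hierarchical clustering of 1 - TOM with size-filtered tree cut.

    Average linkage on the TOM dissimilarity; branches are cut either at
    an explicit static `cut_height`, or (default) by a branch-adaptive
    dynamic procedure that trims undersized side branches to background
    and splits a branch only where the split increases the weighted
    modularity of the TOM graph — robust to the compression of TOM
    values toward zero at high soft-threshold powers and to modules of
    unequal tightness. `deep_split` (0-4, default 2) biases how eagerly
    branches are split. Clusters smaller than `min_module_size` fall to
    background, and an optional hybrid stage reassigns background genes
    that are topologically indistinguishable from module members.
    Deterministic. Module labels are "M1", "M2", ... in decreasing size
    order.
    """
    tom = cons_tom.values
    genes = cons_tom.gene_ids or list(range(tom.shape[0]))
    n = tom.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all background")
        return ModulePartition(assignment=pd.Series(BACKGROUND, index=genes))

    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        labels = _modular_tree_cut(Z, tom, min_module_size, deep_split)
    else:
        raw = cut_tree(Z, height=cut_height).ravel()
        labels = np.full(n, -1, dtype=int)
        uniq, counts = np.unique(raw, return_counts=True)
        for u, c in zip(uniq, counts):
            if c >= min_module_size:
                labels[raw == u] = u
    if hybrid:
        labels = _prune_and_admit(tom, labels, attach_frac, min_module_size)
    # cohesion filter: a module must be visibly tighter than the typical
    # gene pair (median off-diagonal TO; the mean is contaminated when
    # modules cover a large share of all pairs)
    iu = np.triu_indices(n, k=1)
    typical = np.median(tom[iu])
    for u in [int(v) for v in np.unique(labels) if v != -1]:
        idx = np.flatnonzero(labels == u)
        sub = tom[np.ix_(idx, idx)]
        within = (sub.sum() - np.trace(sub)) / max(len(idx) * (len(idx) - 1), 1)
        if within < cohesion * typical:
            labels[idx] = -1
    keep = [int(u) for u in np.unique(labels) if u != -1]

    # rename to M1.. by decreasing size (ties by first-gene position)
    sizes = {m: int((labels == m).sum()) for m in keep}
    first_pos = {m: int(np.flatnonzero(labels == m)[0]) for m in keep if sizes[m] > 0}
    ordered = sorted(sizes, key=lambda m: (-sizes[m], first_pos.get(m, n)))
    name = {m: f"M{i + 1}" for i, m in enumerate(ordered)}
    out = pd.Series([name.get(l, BACKGROUND) if l != -1 else BACKGROUND for l in labels], index=genes)
    log.info("cluster_modules: %d modules, %d background genes",
             len(ordered), int((out == BACKGROUND).sum()))
    return ModulePartition(assignment=out)


def module_eigengene(expr: pd.DataFrame, genes) -> tuple[pd.Series, float]:
    """First principal component of the gene-standardized module block.

    Returns the eigengene scaled to unit variance across samples and the
    fraction of variance it explains. The sign is oriented so that its
    correlation with the module's mean standardized expression is >= 0
    (tie-break: positive correlation with the first gene).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("module must have >= 2 genes")
    X = expr.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant gene(s) dropped from eigengene")
        X = X[~const]
        sd = sd[~const]
        if X.shape[0] < 2:
            raise ValueError("too few non-constant genes for an eigengene")
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples as observations -> left singular vectors over samples of Xs.T
    U, S, _ = np.linalg.svd(Xs.T / np.sqrt(Xs.shape[1]), full_matrices=False)
    pc = U[:, 0]
    var_explained = float(S[0] ** 2 / np.sum(S**2))
    pc = pc / pc.std(ddof=1)
    mean_profile = Xs.mean(axis=0)
    orient = np.dot(pc, mean_profile - mean_profile.mean())
    if orient == 0:
        orient = np.dot(pc, Xs[0] - Xs[0].mean())
    if orient < 0:
        pc = -pc
    return pd.Series(pc, index=expr.columns, name="eigengene"), var_explained


def eigengene_matrix(expr: pd.DataFrame, partition: ModulePartition) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes for every (non-background) module: module x sample."""
    rows, ve = {}, {}
    for m in partition.labels:
        eg, v = module_eigengene(expr, partition.genes_of(m))
        rows[m] = eg
        ve[m] = v
    eigen = pd.DataFrame(rows).T
    eigen.columns = expr.columns
    return eigen, pd.Series(ve, name="var_explained")


def merge_modules(
    expr: pd.DataFrame,
    partition: ModulePartition,
    merge_cut: float = 0.25,
) -> tuple[ModulePartition, pd.DataFrame, pd.Series]:
    """Merge modules whose eigengene dissimilarity 1 - cor < merge_cut.

    The globally closest pair is merged each round (label ties break
    lexicographically, so the outcome is label-permutation invariant up
    to naming), eigengenes are recomputed, and merging repeats to a
    fixed point. Returns the final partition, eigengenes and
    var_explained.
    """
    part = ModulePartition(assignment=partition.assignment.copy())
    while True:
        labels = part.labels
        eigen, ve = eigengene_matrix(expr, part)
        if len(labels) < 2:
            return part, eigen, ve
        C = np.corrcoef(eigen.to_numpy())
        diss = 1.0 - C
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            return part, eigen, ve
        a, b = sorted((labels[i], labels[j]))
        log.info("merging module %s into %s (eigengene diss %.3f)", b, a, diss[i, j])
        new = part.assignment.replace({b: a})
        part = ModulePartition(assignment=new)


def refine_by_kme(
    expr: pd.DataFrame,
    partition: ModulePartition,
    kme_threshold: float = 0.4,
    min_module_size: int = 30,
    n_iter: int = 2,
) -> ModulePartition:
    """Reassign genes by module membership (kME).

    Module eigengenes summarize each detected module; every gene then
    joins the module whose eigengene it correlates with most (bicor),
    provided that correlation reaches kme_threshold, and falls to
    background otherwise. Eigengenes are recomputed and the step
    repeated n_iter times. Modules shrinking below min_module_size
    dissolve. This sharpens the topological cores found by tree
    cutting: with few samples, a gene's correlation with a well-
    estimated eigengene separates members from bystanders better than
    its mean topological overlap does.
    """
    from .network import bicor_matrix

    part = ModulePartition(assignment=partition.assignment.copy())
    X = expr.to_numpy(dtype=float)
    for _ in range(n_iter):
        labels = part.labels
        if not labels:
            return part
        eigen, _ = eigengene_matrix(expr, part)
        E = eigen.to_numpy(dtype=float)
        full = bicor_matrix(np.vstack([X, E]))
        kme = full[: X.shape[0], X.shape[0]:]  # genes x modules
        best = kme.argmax(axis=1)
        best_val = kme[np.arange(len(best)), best]
        new = np.where(best_val >= kme_threshold,
                       np.asarray(labels, dtype=object)[best], BACKGROUND)
        assign = pd.Series(new, index=expr.index)
        for m in labels:
            if (assign == m).sum() < min_module_size:
                assign[assign == m] = BACKGROUND
        if assign.equals(part.assignment):
            break
        part = ModulePartition(assignment=assign)
    return part


def filter_noise_modules(
    expr: pd.DataFrame,
    partition: ModulePartition,
    mp_factor: float = 2.75,
) -> ModulePartition:
    """Dissolve modules indistinguishable from selected noise.

    With few samples, clustering genuinely finds gene sets aligned with
    random directions of sample space; their eigengene explains little
    variance. A module of size m over S samples is kept only if its
    var_explained exceeds mp_factor times the Marchenko-Pastur-style
    noise ceiling (1 + sqrt(m/S))^2 / m — the leading-eigenvalue share
    expected for a pure-noise gene set of that shape.
    """
    assign = partition.assignment.copy()
    n_samples = expr.shape[1]
    for m in partition.labels:
        genes = partition.genes_of(m)
        if len(genes) < 2:
            continue
        _, ve = module_eigengene(expr, genes)
        ceiling = (1.0 + np.sqrt(len(genes) / n_samples)) ** 2 / len(genes)
        if ve < mp_factor * ceiling:
            log.info("module %s (size %d) var_explained %.3f below noise "
                     "ceiling %.3f; dissolved", m, len(genes), ve,
                     mp_factor * ceiling)
            assign[assign == m] = BACKGROUND
    return ModulePartition(assignment=assign)


def validate_modules(
    cons_tom: TOMatrix,
    partition: ModulePartition,
    n_resample: int = 100,
    seed: int = 0,
) -> ModuleValidation:
    """One-proportion Z-test of module coherence against random gene sets.

    Per module: the observed statistic is the mean off-diagonal TO among
    module genes; each resample draws a uniformly random gene set of the
    same size and recomputes it. With p_hat the fraction of resamples
    whose statistic is higher, Z = (p_hat - 0.5)/sqrt(0.25/n_resample)
    and the one-sided p tests the alternative p < 0.5 (random modules
    are rarely tighter than the real one).
    """
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    tom = cons_tom.values
    genes = list(cons_tom.gene_ids or range(tom.shape[0]))
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    n = len(genes)
    rows = []
    for m in partition.labels:
        members = [index_of[g] for g in partition.genes_of(m)]
        if len(members) < 2:
            warnings.warn(f"module {m} has a single gene; validation skipped")
            continue
        sub = tom[np.ix_(members, members)]
        size = len(members)
        obs = (sub.sum() - size) / (size * (size - 1))
        higher = 0
        for _ in range(n_resample):
            pick = rng.choice(n, size=size, replace=False)
            rsub = tom[np.ix_(pick, pick)]
            stat = (rsub.sum() - size) / (size * (size - 1))
            if stat > obs:
                higher += 1
        p_hat = higher / n_resample
        z = (p_hat - 0.5) / np.sqrt(0.25 / n_resample)
        p = float(norm.cdf(z))
        rows.append({"module": m, "mean_to_observed": obs, "n_resamples": n_resample,
                     "n_random_higher": higher, "p_hat": p_hat, "z": z, "p": p})
    return ModuleValidation(table=pd.DataFrame(rows).set_index("module"))


def intramodular_connectivity(adj: np.ndarray, partition: ModulePartition, gene_ids=None) -> pd.DataFrame:
    """k_in per gene: summed adjacency to the other genes of its module.

    Background genes get k_in over the background set and are flagged
    non-hub-eligible.
    """
    genes = list(gene_ids) if gene_ids is not None else list(partition.assignment.index)
    assign = partition.assignment.reindex(genes)
    A = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k_in = np.zeros(len(genes))
    for m in assign.unique():
        idx = np.flatnonzero((assign == m).to_numpy())
        k_in[idx] = A[np.ix_(idx, idx)].sum(axis=1)
    return pd.DataFrame({"module": assign.to_numpy(), "k_in": k_in,
                         "hub_eligible": (assign != BACKGROUND).to_numpy()}, index=genes)


def find_hub_genes(connectivity: pd.DataFrame) -> pd.DataFrame:
    """Flag hubs: within-module connectivity Z-score above 2.

    z_k uses the sample standard deviation (ddof=1); modules with zero
    within-module spread yield no hubs. Returns the table with z_k and
    is_hub columns added; hubs rank by z_k descending within module.
    """
    out = connectivity.copy()
    out["z_k"] = np.nan
    out["is_hub"] = False
    for m, block in out.groupby("module"):
        if m == BACKGROUND or len(block) < 2:
            continue
        sd = block["k_in"].std(ddof=1)
        if sd == 0:
            log.info("module %s: zero connectivity spread, no hubs", m)
            continue
        z = (block["k_in"] - block["k_in"].mean()) / sd
        out.loc[block.index, "z_k"] = z
        out.loc[block.index, "is_hub"] = (z > 2) & block["hub_eligible"]
    return out
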