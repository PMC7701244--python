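"""Synthetic paired RNA/Ribo count data with planted network structure.

The generator emulates the design of the hypertrophy study the pipeline
is built for: 15 samples in four groups (swim 2d n=3, swim 2w n=3, TAC
2d n=4, TAC 2w n=5), with the two assays (RNA-seq transcriptome,
Ribo-seq translatome) driven by shared latent module factors. Each
module has a latent factor per assay; preserved modules share the
factor across assays, non-preserved modules draw an independent Ribo
factor (or are optionally dissolved to background in the Ribo assay —
the construction under which a module is topologically non-preserved).
Gene log-expression loads on its module factor with a loading drawn
from module_membership_range (planted hubs at the top of the range);
counts are negative binomial on a log link with per-sample library
sizes, and an optional gene-wise log-scale batch shift. A controllable
number of genes is "rewired": they keep their RNA module but load on a
different module's factor in the Ribo assay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import log
from .modules import BACKGROUND

__all__ = [
    "SynthConfig",
    "SynthGroundTruth",
    "generate_latent_factors",
    "generate_counts",
    "inject_rewiring",
    "simulate_dataset",
    "write_dataset",
]

GROUPS = ("swim2d", "swim2w", "tac2d", "tac2w")
DEFAULT_SAMPLES = {"swim2d": 3, "swim2w": 3, "tac2d": 4, "tac2w": 5}


@dataclass
class SynthConfig:
    """Parameters of the paired synthetic dataset.

    module_sizes must sum to <= n_genes; the remainder are background
    genes with zero loading. trait_effects maps module index (0-based)
    to the signed shift (in factor sd units) of the pathological (TAC)
    groups' latent-factor mean. preserved_fraction is the fraction of
    modules (from the first) whose factor is shared across assays.
    n_rewired genes keep their RNA module but load on another module's
    factor in the Ribo assay. nb_dispersion is the negative-binomial
    dispersion alpha (var = mu + alpha mu^2). signal_sd is the log2-scale
    biological standard deviation of module genes.
    """

    n_genes: int = 1500
    n_modules: int = 6
    module_sizes: tuple = (150, 120, 100, 90, 80, 60)
    samples_per_group: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    module_membership_range: tuple = (0.6, 0.95)
    trait_effects: dict = field(default_factory=lambda: {
        0: 3.0, 1: -3.0, 2: (2.5, "early"), 3: 0.0, 4: (-2.5, "late"), 5: 0.0})
    preserved_fraction: float = 1.0
    n_rewired: int = 0
    nb_dispersion: float = 0.1
    library_size_range: tuple = (5e5, 1.5e6)
    batch_assignment: dict | None = None
    signal_sd: float = 1.5
    baseline_log2_range: tuple = (4.0, 10.0)
    batch_sd: float = 0.5
    n_hubs_per_module: int = 2
    hub_gap: float = 1.0
    dissolve_unpreserved: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must list one size per module")
        if any(s < 3 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 3")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not 0.0 <= self.preserved_fraction <= 1.0:
            raise ValueError("preserved_fraction must be in [0, 1]")
        if self.n_rewired > sum(self.module_sizes):
            raise ValueError("n_rewired exceeds number of module genes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if min(self.library_size_range) <= 0:
            raise ValueError("library sizes must be positive")
        lo, hi = self.module_membership_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("module_membership_range must be within (0, 1]")

    @property
    def module_labels(self) -> list:
        return [f"M{i + 1}" for i in range(self.n_modules)]

    @property
    def sample_ids(self) -> list:
        out = []
        for g in GROUPS:
            out += [f"{g}_{i + 1}" for i in range(self.samples_per_group.get(g, 0))]
        return out

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series(
            {s: s.rsplit("_", 1)[0] for s in self.sample_ids}, name="group4"
        )

    @property
    def preserved_modules(self) -> list:
        k = int(round(self.preserved_fraction * self.n_modules))
        return self.module_labels[:k]


@dataclass
class SynthGroundTruth:
    """Planted structure: partitions, rewired genes, hubs, factors, traits."""

    partition_rna: pd.Series
    partition_ribo: pd.Series
    rewired_genes: list
    preserved_modules: list
    hub_genes: dict
    latent_factors: dict  # assay -> module x sample DataFrame
    trait_table: pd.DataFrame
    loadings: pd.Series
    dissolved_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "partition_rna": self.partition_rna.to_dict(),
            "partition_ribo": self.partition_ribo.to_dict(),
            "rewired_genes": list(self.rewired_genes),
            "preserved_modules": list(self.preserved_modules),
            "hub_genes": {m: list(v) for m, v in self.hub_genes.items()},
            "latent_factors": {a: df.to_dict() for a, df in self.latent_factors.items()},
            "trait_table": self.trait_table.to_dict(),
            "loadings": self.loadings.to_dict(),
            "dissolved_genes": list(self.dissolved_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _metadata(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for s in config.sample_ids:
        g4 = s.rsplit("_", 1)[0]
        group = "tac" if g4.startswith("tac") else "swim"
        timepoint = "2d" if g4.endswith("2d") else "2w"
        batch = (config.batch_assignment or {}).get(s, "b0")
        rows.append({"sample": s, "group": group, "timepoint": timepoint,
                     "group4": g4, "batch": batch})
    return pd.DataFrame(rows).set_index("sample")


def _orthogonal_noise(rng: np.random.Generator, n_samples: int, basis: list) -> np.ndarray:
    """A centered noise vector orthogonal to the vectors in `basis`.

    Used so that the planted factors of different modules are distinct
    by construction: incidental finite-sample correlation between two
    biologically unrelated factors would make the planted partition
    ill-defined at 15 samples. Falls back to a plain centered draw once
    the sample space is exhausted.
    """
    for _ in range(50):
        v = rng.standard_normal(n_samples)
        for b in basis:
            v = v - np.dot(v, b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm * np.sqrt(n_samples)
    v = rng.standard_normal(n_samples)
    return (v - v.mean()) / v.std(ddof=0)


def _effect_shift(effect, samples) -> np.ndarray:
    """Group-shift vector for one module's trait effect.

    `effect` is a scalar (sustained shift of all TAC samples) or a pair
    (magnitude, pattern) with pattern "sustained", "early" (TAC 2d only)
    or "late" (TAC 2w only) — modules in a remodeling heart respond on
    different time scales.
    """
    if isinstance(effect, (tuple, list)):
        mag, pattern = float(effect[0]), str(effect[1])
    else:
        mag, pattern = float(effect), "sustained"
    sel = {"sustained": lambda s: s.startswith("tac"),
           "early": lambda s: s.startswith("tac2d"),
           "late": lambda s: s.startswith("tac2w")}
    if pattern not in sel:
        raise ValueError(f"unknown effect pattern: {pattern}")
    return mag * np.array([sel[pattern](s) for s in samples], dtype=float)


def generate_latent_factors(config: SynthConfig, rng: np.random.Generator) -> dict:
    """Per-assay module x sample latent factors, standardized per module.

    The noise parts of the factors are drawn mutually orthogonal (and
    orthogonal to the constant vector), so planted modules stay
    statistically distinguishable at small n; trait effects then shift
    the group means before standardization. Preserved modules reuse the
    RNA factor in the Ribo assay, the rest draw an independent Ribo
    factor with the same trait effect.
    """
    samples = config.sample_ids
    if any(config.samples_per_group.get(g, 0) < 2 for g in GROUPS if config.samples_per_group.get(g, 0) > 0):
        raise ValueError("every non-empty group needs >= 2 samples")
    if len(samples) < 4:
        raise ValueError("need at least 4 samples overall")
    n_s = len(samples)
    ones = np.ones(n_s) / np.sqrt(n_s)

    preserved = set(config.preserved_modules)
    fac_rna, fac_ribo = {}, {}
    basis = [ones]
    for i, m in enumerate(config.module_labels):
        eff = config.trait_effects.get(i, config.trait_effects.get(m, 0.0))
        z = _orthogonal_noise(rng, n_s, basis)
        basis.append(z / np.linalg.norm(z))
        f = z + _effect_shift(eff, samples)
        fac_rna[m] = (f - f.mean()) / f.std(ddof=0)
    ribo_basis = [ones]
    for i, m in enumerate(config.module_labels):
        if m in preserved:
            fac_ribo[m] = fac_rna[m]
            ribo_basis.append(fac_rna[m] / np.linalg.norm(fac_rna[m]))
    for i, m in enumerate(config.module_labels):
        if m not in preserved:
            eff = config.trait_effects.get(i, config.trait_effects.get(m, 0.0))
            z = _orthogonal_noise(rng, n_s, ribo_basis)
            ribo_basis.append(z / np.linalg.norm(z))
            f = z + _effect_shift(eff, samples)
            fac_ribo[m] = (f - f.mean()) / f.std(ddof=0)
    to_df = lambda d: pd.DataFrame(d, index=samples).T
    return {"rna": to_df({m: to for m, to in fac_rna.items()}),
            "ribo": to_df({m: fac_ribo[m] for m in config.module_labels})}


def _base_partition(config: SynthConfig) -> pd.Series:
    labels = []
    for m, size in zip(config.module_labels, config.module_sizes):
        labels += [m] * size
    labels += [BACKGROUND] * (config.n_genes - len(labels))
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    return pd.Series(labels, index=genes, name="module")


def inject_rewiring(
    partition_rna: pd.Series,
    config: SynthConfig,
    rng: np.random.Generator,
    loadings: pd.Series | None = None,
) -> tuple[pd.Series, list]:
    """Reassign n_rewired genes to a different module's factor in Ribo.

    Rewired genes keep their RNA label and full loading, so they stay
    well connected in both assays. When loadings are given, candidates
    are restricted to the upper-loading half of each module (planted
    hubs included) — rewiring of a weakly connected gene leaves no
    detectable network signature, and in the motivating data the most
    rewired genes sat in the well-connected cores of the top preserved
    modules. Returns the Ribo partition and the rewired gene list.
    """
    partition_ribo = partition_rna.copy()
    eligible = list(partition_rna.index[partition_rna != BACKGROUND])
    if loadings is not None:
        eligible = [g for g in eligible
                    if loadings[g] >= loadings[partition_rna.index[
                        partition_rna == partition_rna[g]]].median()]
    if config.n_rewired > len(eligible):
        raise ValueError("n_rewired exceeds eligible genes")
    if config.n_rewired == 0 or config.n_modules < 2:
        return partition_ribo, []
    picked = sorted(rng.choice(len(eligible), size=config.n_rewired, replace=False))
    rewired = [eligible[i] for i in picked]
    labels = config.module_labels
    for g in rewired:
        current = partition_rna[g]
        others = [m for m in labels if m != current]
        partition_ribo[g] = others[rng.integers(len(others))]
    return partition_ribo, rewired


def generate_counts(
    factors: pd.DataFrame,
    partition: pd.Series,
    loadings: pd.Series,
    baselines: pd.Series,
    library_sizes: pd.Series,
    metadata: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Negative-binomial counts for one assay from its latent factors.

    Gene g in module M has log2-scale signal mu_g + s*(lambda_g f_M +
    sqrt(1-lambda_g^2) eps), so the latent gene-factor correlation is
    lambda_g; background genes have lambda = 0. Expected counts are the
    per-sample library size times the sample-normalized linear-scale
    abundance; dispersion alpha gives var = mu + alpha mu^2 (gamma-
    Poisson; alpha ~ 0 collapses to Poisson). Batch adds a gene-wise
    log2 shift per batch.
    """
    if config.nb_dispersion < 0 or (library_sizes <= 0).any():
        raise ValueError("non-positive dispersion or library size")
    genes = list(partition.index)
    samples = list(factors.columns)
    n_g, n_s = len(genes), len(samples)
    lam = loadings.reindex(genes).to_numpy()
    # compensate the loading for count-level noise so the realized
    # log-scale gene-factor correlation lands near the nominal loading:
    # with signal sd s and log2-NB noise variance v, cor = s*lam'/sqrt(s^2+v)
    q0 = np.exp2(baselines.reindex(genes).to_numpy())
    q0 = q0 / q0.sum()
    mu0 = q0[:, None] * library_sizes.reindex(samples).to_numpy()[None, :]
    v_noise = (1.0 / np.maximum(mu0.mean(axis=1), 1.0) + config.nb_dispersion) / np.log(2.0) ** 2
    s2 = config.signal_sd**2
    if s2 > 0:
        lam = np.minimum(1.0, lam * np.sqrt(1.0 + v_noise / s2))
    F = np.zeros((n_g, n_s))
    for m in factors.index:
        sel = (partition == m).to_numpy()
        F[sel] = factors.loc[m].to_numpy()
    eps = rng.standard_normal((n_g, n_s))
    y = (
        baselines.reindex(genes).to_numpy()[:, None]
        + config.signal_sd * (lam[:, None] * F + np.sqrt(1.0 - lam[:, None] ** 2) * eps)
    )
    batches = metadata["batch"].reindex(samples)
    if batches.nunique() > 1:
        for b in sorted(batches.unique()):
            shift = rng.normal(0.0, config.batch_sd, size=n_g)
            y[:, (batches == b).to_numpy()] += shift[:, None]
    q = np.exp2(y)
    q = q / q.sum(axis=0, keepdims=True)
    mu = q * library_sizes.reindex(samples).to_numpy()[None, :]
    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        lam_gp = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        counts = rng.poisson(lam_gp)
    return pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)


def simulate_dataset(config: SynthConfig):
    """Generate the paired dataset: counts per assay, metadata, ground truth.

    Returns (counts_rna, counts_ribo, metadata, ground_truth). A single
    seeded generator drives every draw, so identical config + seed give
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    metadata = _metadata(config)
    partition_rna = _base_partition(config)
    factors = generate_latent_factors(config, rng)

    lo, hi = config.module_membership_range
    lam = pd.Series(0.0, index=partition_rna.index)
    hub_genes = {}
    for m, size in zip(config.module_labels, config.module_sizes):
        members = list(partition_rna.index[partition_rna == m])
        n_hub = min(config.n_hubs_per_module, size)
        # hubs own the top of the membership range; hub_gap < 1 confines
        # the rest to its lower part, leaving a margin wider than the
        # correlation noise at 15 samples so "top-loading gene" stays an
        # identifiable ground truth
        draws = np.sort(rng.uniform(lo, lo + config.hub_gap * (hi - lo), size=size))[::-1]
        draws[:n_hub] = hi
        lam[members] = draws
        hub_genes[m] = members[:n_hub]

    partition_ribo, rewired = inject_rewiring(partition_rna, config, rng, loadings=lam)

    dissolved = []
    lam_ribo = lam.copy()
    partition_ribo_eff = partition_ribo.copy()
    if config.dissolve_unpreserved:
        preserved = set(config.preserved_modules)
        for m in config.module_labels:
            if m not in preserved:
                members = list(partition_rna.index[partition_rna == m])
                lam_ribo[members] = 0.0
                partition_ribo_eff[members] = BACKGROUND
                dissolved += members
        log.info("dissolved %d genes of non-preserved modules in Ribo", len(dissolved))

    baselines = pd.Series(
        rng.uniform(*config.baseline_log2_range, size=config.n_genes),
        index=partition_rna.index,
    )
    lo_lib, hi_lib = config.library_size_range
    lib_rna = pd.Series(rng.uniform(lo_lib, hi_lib, size=len(config.sample_ids)), index=config.sample_ids)
    lib_ribo = pd.Series(rng.uniform(lo_lib, hi_lib, size=len(config.sample_ids)), index=config.sample_ids)

    counts_rna = generate_counts(factors["rna"], partition_rna, lam, baselines,
                                 lib_rna, metadata, config, rng)
    counts_ribo = generate_counts(factors["ribo"], partition_ribo_eff, lam_ribo, baselines,
                                  lib_ribo, metadata, config, rng)

    is_tac = metadata["group"] == "tac"
    trait_table = pd.DataFrame({
        "pathological_vs_physiological": is_tac.astype(float),
        "hwbw": 5.0 + 2.0 * is_tac.astype(float) + rng.normal(0, 0.3, len(metadata)),
    }, index=metadata.index)
    metadata = metadata.assign(hwbw=trait_table["hwbw"])

    gt = SynthGroundTruth(
        partition_rna=partition_rna,
        partition_ribo=partition_ribo_eff,
        rewired_genes=rewired,
        preserved_modules=config.preserved_modules,
        hub_genes=hub_genes,
        latent_factors=factors,
        trait_table=trait_table,
        loadings=lam,
        dissolved_genes=dissolved,
    )
    return counts_rna, counts_ribo, metadata, gt


def write_dataset(outdir, counts_rna, counts_ribo, metadata, gt: SynthGroundTruth) -> None:
    """Write counts, metadata and ground truth to a directory (TSV/JSON)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    counts_rna.to_csv(os.path.join(outdir, "counts_rna.tsv"), sep="\t")
    counts_ribo.to_csv(os.path.join(outdir, "counts_ribo.tsv"), sep="\t")
    metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")
    gt.to_json(os.path.join(outdir, "ground_truth.json"))
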