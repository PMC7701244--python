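"""Shared fixtures: synthetic paired studies at several scales.

The expensive fixtures (bootstrap-consensus TOMs) are session-scoped so
that several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import corewire as cw


@pytest.fixture(scope="session")
def small_study():
    """A small paired dataset with 4 planted modules, no rewiring."""
    cfg = cw.SynthConfig(
        n_genes=400, n_modules=4, module_sizes=(60, 50, 40, 40),
        trait_effects={0: 3.0, 1: -3.0, 2: 2.0, 3: 0.0}, seed=7,
    )
    counts_rna, counts_ribo, metadata, gt = cw.simulate_dataset(cfg)
    expr_rna, expr_ribo = cw.preprocess_pair(
        cw.CountMatrix(counts_rna, "RNA"), cw.CountMatrix(counts_ribo, "Ribo")
    )
    return {"config": cfg, "metadata": metadata, "truth": gt,
            "expr_rna": expr_rna, "expr_ribo": expr_ribo}


@pytest.fixture(scope="session")
def recovery_study():
    """The module-recovery benchmark: 1,500 genes, 6 modules of 60-150
    genes, membership 0.6-0.95, the 15-sample 4-group design, and 20
    rewired genes; consensus TOMs at n_boot=100 per assay."""
    cfg = cw.SynthConfig(
        n_genes=1500, n_modules=6, module_sizes=(150, 130, 110, 90, 75, 60),
        module_membership_range=(0.6, 0.95), n_rewired=20, seed=11,
    )
    counts_rna, counts_ribo, metadata, gt = cw.simulate_dataset(cfg)
    expr_rna, expr_ribo = cw.preprocess_pair(
        cw.CountMatrix(counts_rna, "RNA"), cw.CountMatrix(counts_ribo, "Ribo")
    )
    groups = metadata["group4"].to_dict()
    toms, parts = {}, {}
    for assay, expr in (("rna", expr_rna), ("ribo", expr_ribo)):
        ncfg = cw.NetworkConfig(beta=18.0, n_boot=100, resample_groups=groups, seed=5)
        toms[assay] = cw.consensus_tom(expr.values, ncfg)
        part = cw.cluster_modules(toms[assay], min_module_size=30)
        part, _, _ = cw.merge_modules(expr.values, part)
        part = cw.refine_by_kme(expr.values, part, 0.4, 30)
        parts[assay] = cw.filter_noise_modules(expr.values, part)
    return {"config": cfg, "metadata": metadata, "truth": gt,
            "expr_rna": expr_rna, "expr_ribo": expr_ribo,
            "toms": toms, "partitions": parts}


@pytest.fixture(scope="session")
def rewiring_study():
    """Strong-module regime for neighborhood-level scores: membership
    0.8-0.95 keeps consensus TO values above the 0.1 edge threshold, so
    thresholded neighborhoods are non-empty; 20 of 1,500 genes rewired."""
    cfg = cw.SynthConfig(
        n_genes=1500, n_modules=6, module_sizes=(350, 300, 250, 200, 120, 80),
        module_membership_range=(0.8, 0.95), n_rewired=20, seed=13,
    )
    counts_rna, counts_ribo, metadata, gt = cw.simulate_dataset(cfg)
    expr_rna, expr_ribo = cw.preprocess_pair(
        cw.CountMatrix(counts_rna, "RNA"), cw.CountMatrix(counts_ribo, "Ribo")
    )
    groups = metadata["group4"].to_dict()
    toms = {}
    for assay, expr in (("rna", expr_rna), ("ribo", expr_ribo)):
        ncfg = cw.NetworkConfig(beta=18.0, n_boot=50, resample_groups=groups, seed=5)
        toms[assay] = cw.consensus_tom(expr.values, ncfg)
    return {"config": cfg, "metadata": metadata, "truth": gt,
            "expr_rna": expr_rna, "expr_ribo": expr_ribo, "toms": toms}
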