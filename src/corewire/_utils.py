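"""Shared helpers: stage-seed derivation, table IO, logging."""

from __future__ import annotations

import hashlib
import logging

import pandas as pd

log = logging.getLogger("corewire")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from the global seed and a stage name.

    Hash-based so that adding a stage never shifts the randomness of the
    others. Result is a non-negative int below 2**31.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def read_table(path) -> pd.DataFrame:
    """Read a delimited table with the first column as index.

    Dialect by extension: .csv is comma-separated, everything else tab.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)
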