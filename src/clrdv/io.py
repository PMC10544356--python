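"""Readers, writers and fixture generation for the clrdv pipeline.

Count matrices are plain TSV/CSV with gene ids in the first column and a
header row of sample ids; labels files are two-column TSV (sample_id,
group).  Everything round-trips losslessly through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import validate_counts
from .simulate import SimDesign, simulate_two_groups, synth_nb2_params

__all__ = [
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "make_fixture",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path, transpose: bool = False) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV/CSV and validate it."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed count file {path}: {exc}") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    validate_counts(df)
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    counts.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"labels file {path} must have exactly 2 columns")
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if labels.index.has_duplicates:
        raise ValueError("duplicate sample id in labels file")
    return labels


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "group": labels.values}).to_csv(
        Path(path), sep="\t", index=False
    )


def make_fixture(kind: str, seed: int, out_dir) -> dict:
    """Write a small synthetic counts/labels/truth fixture; returns file paths.

    Kinds: ``tiny`` (50 genes, 40+40 samples, no DV genes), ``null``
    (200 genes, 100+100, no DV), ``spiked`` (200 genes, 100+100, 10% DV).
    """
    designs = {
        "tiny": SimDesign(G=50, prop_dv=0.0, n_per_group=40, seed=seed),
        "null": SimDesign(G=200, prop_dv=0.0, n_per_group=100, seed=seed),
        "spiked": SimDesign(G=200, prop_dv=0.1, n_per_group=100, seed=seed),
    }
    if kind not in designs:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {list(designs)}")
    design = designs[kind]
    params = synth_nb2_params(design.G, seed)
    counts, truth, gdesign = simulate_two_groups(params, design)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / f"{kind}_counts.tsv",
        "labels": out_dir / f"{kind}_labels.tsv",
        "truth": out_dir / f"{kind}_truth.tsv",
    }
    write_counts(counts, paths["counts"])
    write_labels(gdesign.labels, paths["labels"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
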