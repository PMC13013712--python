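"""File formats: counts as TSV or MatrixMarket, metadata / spot / score TSVs, GMT gene sets.

All formats are plain text. Counts round-trip through either a TSV with
genes as rows and sample IDs as the header, or a MatrixMarket ``.mtx``
with ``genes.txt`` / ``samples.txt`` sidecars.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .countcore import CountMatrix

META_COLUMNS = ["sample_id", "grade", "vi", "batch", "tumor_id", "region_id"]


def write_counts_tsv(cm: CountMatrix, path: str) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.index.to_numpy(object), df.columns.to_numpy(object),
                       df.to_numpy())


def write_counts_mtx(cm: CountMatrix, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    scipy.io.mmwrite(os.path.join(dirpath, "counts.mtx"),
                     scipy.sparse.coo_matrix(cm.counts))
    with open(os.path.join(dirpath, "genes.txt"), "w") as fh:
        fh.write("\n".join(map(str, cm.gene_ids)) + "\n")
    with open(os.path.join(dirpath, "samples.txt"), "w") as fh:
        fh.write("\n".join(map(str, cm.sample_ids)) + "\n")


def read_counts_mtx(dirpath: str) -> CountMatrix:
    counts = scipy.io.mmread(os.path.join(dirpath, "counts.mtx")).toarray()
    genes = np.loadtxt(os.path.join(dirpath, "genes.txt"), dtype=object, ndmin=1)
    samples = np.loadtxt(os.path.join(dirpath, "samples.txt"), dtype=object, ndmin=1)
    return CountMatrix(genes, samples, counts.astype(np.int64))


def write_meta(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    return meta


def write_scores(scores: pd.DataFrame, path: str) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: dict, path: str) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(truth, fh, default=_default, indent=1)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")
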