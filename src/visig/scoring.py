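"""Signature scores for samples and spots.

Three scoring schemes are used downstream of the signature: the mean
z-score of a gene cluster per sample; an expression-bin-controlled module
score per spot (mean set expression minus mean expression of matched
control genes); and the up-minus-down combination of predictor-gene module
scores used on spatial data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "mean_zscore_score",
    "module_score",
    "predictor_spot_score",
    "log_normalize_counts",
]


def _score_table(unit_ids, name: str, values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"unit_id": np.asarray(unit_ids, dtype=object),
                         "score": name, "value": values})


def mean_zscore_score(z: np.ndarray, gene_ids, gene_set, sample_ids,
                      name: str = "mean_z") -> pd.DataFrame:
    """Per-sample mean z-score over the genes of a set.

    Set genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in gene_set if g in pos]
    missing = len(list(gene_set)) - len(present)
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if missing:
        warnings.warn(f"{missing} set gene(s) absent from the matrix; dropped")
    idx = np.array([pos[g] for g in present])
    return _score_table(sample_ids, name, np.asarray(z, float)[idx].mean(axis=0))


def log_normalize_counts(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log1p of depth-normalized counts (unit x gene), scale 1e4."""
    depth = counts.sum(axis=1).to_numpy(float)
    if np.any(depth <= 0):
        raise ValueError("unit with zero total counts")
    return np.log1p(counts.div(depth, axis=0) * scale)


def module_score(expr: pd.DataFrame, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0,
                 name: str = "module") -> pd.DataFrame:
    """Expression-bin-controlled module score per unit (spot or sample).

    Genes are assigned to ``n_bins`` equal-frequency bins of average
    expression across units (ties to the lower bin); each set gene draws
    ``n_ctrl`` control genes with replacement from its bin; the score is
    the mean expression of the set minus the mean expression of the
    controls, per unit.
    """
    genes = expr.columns.to_numpy(object)
    present = [g for g in gene_set if g in set(genes)]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    if len(present) < len(list(gene_set)):
        warnings.warn("some set genes absent from the matrix; dropped")
    if len(genes) <= n_bins:
        raise ValueError("need more genes than bins")
    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=0)
    # equal-frequency bins on the rank of average expression, ties low
    ranks = avg.rank(method="first").to_numpy()
    bins = np.minimum(((ranks - 1) * n_bins / len(genes)).astype(int), n_bins - 1)
    bin_of = dict(zip(genes, bins))
    bin_members = {b: genes[bins == b] for b in range(n_bins)}

    X = expr.to_numpy(float)
    col = {g: i for i, g in enumerate(genes)}
    set_idx = np.array([col[g] for g in present])
    ctrl_sum = np.zeros(X.shape[0])
    for g in present:
        members = bin_members[bin_of[g]]
        picks = rng.choice(members, size=n_ctrl, replace=True)
        ctrl_sum += X[:, [col[c] for c in picks]].mean(axis=1)
    score = X[:, set_idx].mean(axis=1) - ctrl_sum / len(present)
    return _score_table(expr.index.to_numpy(object), name, score)


def predictor_spot_score(expr: pd.DataFrame, up_set, down_set,
                         n_bins: int = 24, n_ctrl: int = 100, seed: int = 0,
                         name: str = "predictor_spot") -> pd.DataFrame:
    """Module score of VI-increased predictor genes minus VI-decreased ones."""
    up = module_score(expr, up_set, n_bins, n_ctrl, seed, name="up")
    down = module_score(expr, down_set, n_bins, n_ctrl, seed, name="down")
    return _score_table(expr.index.to_numpy(object), name,
                        up["value"].to_numpy() - down["value"].to_numpy())
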