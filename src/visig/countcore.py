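"""Count-matrix container, TMM normalization, CPM transforms and per-gene scaling.

The quantitative backbone of the pipeline: raw gene-by-sample counts are
normalized for sequencing depth and library composition (trimmed mean of
M-values), converted to log2 counts per million, and standardized per gene
for clustering and signature scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "LogCpmMatrix",
    "tmm_factors",
    "filter_genes",
    "log_cpm",
    "zscore_by_gene",
]


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count matrix.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique identifiers for rows and columns.
    counts
        ``(n_genes, n_samples)`` array of non-negative integers.
    lib_sizes
        Per-sample library sizes; column sums of ``counts`` unless overridden.
    norm_factors
        Per-sample composition normalization factors (TMM); default 1.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray
    lib_sizes: np.ndarray | None = None
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if np.any(self.lib_sizes <= 0):
            raise ValueError("lib_sizes must be positive")
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.sample_ids))
        else:
            self.norm_factors = np.asarray(self.norm_factors, dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cpm(self) -> np.ndarray:
        """Counts per million using raw library sizes (no prior, no TMM)."""
        return self.counts / self.lib_sizes * 1e6

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        if np.asarray(mask_or_ids).dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in mask_or_ids])
        return CountMatrix(
            self.gene_ids[idx], self.sample_ids.copy(), self.counts[idx],
            lib_sizes=self.lib_sizes.copy(), norm_factors=self.norm_factors.copy(),
        )

    def subset_samples(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.gene_ids.copy(), self.sample_ids[idx], self.counts[:, idx],
            lib_sizes=self.lib_sizes[idx], norm_factors=self.norm_factors[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class LogCpmMatrix:
    """log2 CPM matrix with the prior count and provenance recorded.

    logCPM = log2((count + prior) / (lib_size * norm_factor + 2 * prior) * 1e6)
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    prior_count: float = 0.5
    source: CountMatrix | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids) -> "LogCpmMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids])
        return LogCpmMatrix(self.gene_ids[idx], self.sample_ids.copy(),
                            self.values[idx], self.prior_count, self.source)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
                     logratio_trim: float = 0.30, abs_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference.

    Doubly trimmed (30% on M-values, 5% on A-values) weighted mean of
    log2 ratios; weights are inverse asymptotic binomial variances.
    Genes with a zero count in either sample are excluded.
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size < 2:
        warnings.warn("fewer than 2 genes usable for TMM; factor set to 1")
        return 1.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, w = m[fin], a[fin], w[fin]
    n = m.size
    if n < 2:
        warnings.warn("fewer than 2 genes survive TMM trimming; factor set to 1")
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # rank-based double trim, as in the canonical published algorithm
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep2.sum() < 2:
        warnings.warn("fewer than 2 genes survive TMM trimming; factor set to 1")
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, ref_sample: int | str | None = None) -> np.ndarray:
    """Per-sample TMM normalization factors, geometric mean rescaled to 1.

    The reference sample, unless given, is the one whose 75th-percentile
    count fraction is closest to the mean across samples.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")
    if np.any(cm.counts.sum(axis=0) == 0):
        raise ValueError("all-zero sample: TMM undefined")
    frac75 = np.array([
        np.quantile(cm.counts[:, j] / cm.lib_sizes[j], 0.75)
        for j in range(cm.n_samples)
    ])
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(frac75 - frac75.mean())))
    elif isinstance(ref_sample, str):
        ref_idx = int(np.flatnonzero(cm.sample_ids == ref_sample)[0])
    else:
        ref_idx = int(ref_sample)
    ref = cm.counts[:, ref_idx]
    n_ref = cm.lib_sizes[ref_idx]
    factors = np.array([
        _tmm_pair_factor(cm.counts[:, j], ref, cm.lib_sizes[j], n_ref)
        for j in range(cm.n_samples)
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def with_tmm(cm: CountMatrix, ref_sample=None) -> CountMatrix:
    """Return a copy of ``cm`` with TMM norm_factors attached."""
    out = replace(cm)
    out.norm_factors = tmm_factors(cm, ref_sample)
    return out


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def filter_genes(cm: CountMatrix, cpm_threshold: float = 1.0,
                 min_fraction: float = 0.10) -> CountMatrix:
    """Keep genes with CPM > threshold in at least ceil(min_fraction * n) samples.

    CPM here uses raw library sizes (pre-TMM, no prior), the convention of
    the expression filter applied before differential expression.
    """
    if cpm_threshold <= 0 or min_fraction <= 0:
        raise ValueError("thresholds must be positive")
    min_n = int(np.ceil(min_fraction * cm.n_samples))
    keep = (cm.cpm() > cpm_threshold).sum(axis=1) >= min_n
    if not keep.any():
        warnings.warn("expression filter removed every gene")
    return cm.subset_genes(keep)


def log_cpm(cm: CountMatrix, prior_count: float = 0.5) -> LogCpmMatrix:
    """log2 counts per million with a prior count, using TMM-adjusted library sizes."""
    eff = cm.lib_sizes * cm.norm_factors
    vals = np.log2((cm.counts + prior_count) / (eff + 2.0 * prior_count)[None, :] * 1e6)
    return LogCpmMatrix(cm.gene_ids.copy(), cm.sample_ids.copy(), vals,
                        prior_count=prior_count, source=cm)


def zscore_by_gene(lcm: LogCpmMatrix | np.ndarray) -> np.ndarray:
    """Standardize each gene across samples to mean 0, sd 1 (ddof=1).

    Genes with zero variance get an all-zero row (with a warning);
    single-sample input is rejected.
    """
    x = lcm.values if isinstance(lcm, LogCpmMatrix) else np.asarray(lcm, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) set to z = 0")
    sd[flat] = 1.0
    z = (x - mu) / sd
    z[flat.nonzero()[0], :] = 0.0
    return z
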