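"""Derivation of the VI co-expression signature.

Differential expression uses a negative-binomial log-link GLM per gene with
library-size offsets and a likelihood-ratio test of the contrast
coefficients (VI vs LMP under the three-level grade factor, optionally with
extra covariates such as lymphatic invasion). Dispersion is a per-gene
method-of-moments estimate shrunk toward a lowess trend on mean logCPM.
Significant genes are grouped by Ward2 hierarchical clustering of per-gene
z-scores, with the number of clusters chosen by consensus clustering
(subsample stability, delta area under the consensus CDF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.special
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .countcore import CountMatrix, log_cpm

__all__ = [
    "DEResult",
    "GeneClusterSignature",
    "grade_design",
    "estimate_dispersions",
    "nb_glm_lrt",
    "bh_adjust",
    "signed_rank_statistic",
    "ward2_cluster",
    "consensus_select_k",
]

_MAX_ITER = 60
_BETA_TOL = 1e-8


@dataclass
class DEResult:
    """Per-gene differential-expression table (log2FC, LRT, p, BH q)."""

    table: pd.DataFrame  # gene_id, log2fc, lrt, df, pvalue, qvalue, mean_logcpm

    def __post_init__(self) -> None:
        t = self.table
        ok = t["pvalue"].notna()
        if np.any(t.loc[ok, "lrt"] < -1e-8):
            raise ValueError("negative LRT statistic")
        if np.any((t.loc[ok, "qvalue"] + 1e-12) < t.loc[ok, "pvalue"]):
            raise ValueError("q-value below p-value")

    def significant(self, fdr: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["qvalue"] < fdr]


@dataclass
class GeneClusterSignature:
    """Gene -> cluster partition of the significant set with directions."""

    genes: list[str]
    labels: np.ndarray            # cluster id in 1..k per gene
    k: int
    directions: dict[int, str]    # cluster -> 'up' | 'down' in VI
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.labels):
            raise ValueError("genes/labels length mismatch")
        if set(np.unique(self.labels)) - set(range(1, self.k + 1)):
            raise ValueError("labels outside 1..k")

    def cluster_members(self, c: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == c]

    def as_gene_sets(self) -> dict[str, list[str]]:
        return {f"cluster{c}": self.cluster_members(c) for c in range(1, self.k + 1)}


def grade_design(meta: pd.DataFrame, covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Design matrix for the 3-level grade factor: intercept + NST + VI dummies.

    LMP is the baseline; the ``VI`` column is the VI-vs-LMP contrast
    coefficient. Extra covariate columns (e.g. an LI indicator) are appended
    as given.
    """
    design = pd.DataFrame({
        "Intercept": np.ones(len(meta)),
        "NST": (meta["grade"] == "NST").astype(float).to_numpy(),
        "VI": (meta["grade"] == "VI").astype(float).to_numpy(),
    }, index=meta["sample_id"].to_numpy())
    for c in covariates:
        design[c] = meta[c].astype(float).to_numpy()
    return design


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(cm: CountMatrix, prior_weight: float = 10.0) -> np.ndarray:
    """Per-gene NB dispersion: method-of-moments shrunk toward a lowess trend.

    Counts are depth-normalized to the mean effective library size; the raw
    estimate ``(var - mean) / mean^2`` is shrunk toward a lowess fit of the
    raw values on mean logCPM. The trend carries ``prior_weight`` pseudo-
    genes of information against the gene's own residual degrees of
    freedom, so with ~100 samples the per-gene estimate dominates and the
    trend mainly stabilizes low-count genes.
    """
    eff = cm.lib_sizes * cm.norm_factors
    x = cm.counts / eff[None, :] * eff.mean()
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / m**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 1e-6, 100.0)
    mean_lcpm = log_cpm(cm).values.mean(axis=1)
    order = np.argsort(mean_lcpm)
    fit = lowess(np.log(raw[order]), mean_lcpm[order], frac=0.4, return_sorted=False)
    trend = np.empty_like(raw)
    trend[order] = np.exp(fit)
    resid_df = max(cm.n_samples - 1, 1)
    shrunk = (prior_weight * trend + resid_df * raw) / (prior_weight + resid_df)
    return np.clip(shrunk, 1e-6, 100.0)


# ---------------------------------------------------------------------------
# NB GLM fitting (batched IRLS across genes, shared design)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood at fixed dispersion (phi per gene)."""
    inv = 1.0 / phi[:, None]
    return (
        scipy.special.gammaln(y + inv) - scipy.special.gammaln(inv)
        - scipy.special.gammaln(y + 1.0)
        + y * np.log(phi[:, None] * mu / (1.0 + phi[:, None] * mu))
        - inv * np.log1p(phi[:, None] * mu)
    ).sum(axis=1)


def _fit_nb_batch(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                  phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-link GLMs for all genes at once by IRLS.

    Returns (loglik, beta, converged). A small ridge damping term keeps the
    working normal equations solvable under separation (e.g. a group with
    all-zero counts).
    """
    G, n = y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # initialize intercept-ish: log mean depth-normalized count
    mu0 = np.maximum(y.mean(axis=1), 0.5)
    eta = np.log(mu0)[:, None] - offset.mean() + np.zeros((G, n)) + offset[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = mu[idx]
        w = mu_a / (1.0 + phi[idx, None] * mu_a)          # working weights
        z = (eta[idx] - offset[None, :]) + (y[idx] - mu_a) / mu_a
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWX += 1e-8 * np.eye(p)[None, :, :] * (1.0 + np.trace(XtWX, axis1=1, axis2=2))[:, None, None] / p
        XtWz = np.einsum("ni,gn,gn->gi", X, w, z)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = new_beta - beta[idx]
        # damp huge steps (separation drift)
        norm = np.abs(step).max(axis=1)
        big = norm > 10.0
        if big.any():
            step[big] *= (10.0 / norm[big])[:, None]
        beta[idx] = beta[idx] + step
        eta[idx] = np.clip(beta[idx] @ X.T, -30.0, 30.0) + offset[None, :]
        mu[idx] = np.exp(np.clip(eta[idx], -30.0, 30.0))
        done = np.abs(step).max(axis=1) < _BETA_TOL
        converged[idx[done]] = True
        active[idx[done]] = False
    ll = _nb_loglik(y, np.maximum(mu, 1e-10), phi)
    return ll, beta, converged


def nb_glm_lrt(cm: CountMatrix, design: pd.DataFrame,
               contrast: str | list[str] = "VI",
               dispersions: np.ndarray | None = None) -> DEResult:
    """Negative-binomial GLM likelihood-ratio test per gene.

    Fits the full design and the design with the contrast column(s)
    dropped, both at the same fixed per-gene dispersion, with offsets
    ``log(lib_size * norm_factor)``; the LRT statistic is referred to a
    chi-squared with as many degrees of freedom as dropped coefficients.
    Non-converged genes are flagged with ``pvalue = NaN`` and excluded from
    the FDR adjustment.
    """
    contrast_cols = [contrast] if isinstance(contrast, str) else list(contrast)
    for c in contrast_cols:
        if c not in design.columns:
            raise ValueError(f"contrast column {c!r} not in design")
    X_full = design.to_numpy(float)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design is not full rank")
    X_red = design.drop(columns=contrast_cols).to_numpy(float)
    df = len(contrast_cols)

    if dispersions is None:
        dispersions = estimate_dispersions(cm)
    y = cm.counts.astype(float)
    offset = np.log(cm.lib_sizes * cm.norm_factors)

    ll_full, beta_full, conv_full = _fit_nb_batch(y, X_full, offset, dispersions)
    ll_red, _, conv_red = _fit_nb_batch(y, X_red, offset, dispersions)
    ok = conv_full & conv_red
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} gene(s) failed to converge; p set to NA")

    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    pval = scipy.stats.chi2.sf(lrt, df)
    pval[~ok] = np.nan
    qval = bh_adjust(pval)
    first_contrast = design.columns.get_loc(contrast_cols[0])
    log2fc = beta_full[:, first_contrast] / np.log(2.0)
    mean_lcpm = log_cpm(cm).values.mean(axis=1)
    table = pd.DataFrame({
        "gene_id": cm.gene_ids,
        "log2fc": log2fc,
        "lrt": lrt,
        "df": df,
        "pvalue": pval,
        "qvalue": qval,
        "mean_logcpm": mean_lcpm,
    })
    return DEResult(table)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaNs are passed through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def signed_rank_statistic(de: DEResult, floor: float | None = None) -> pd.Series:
    """Per-gene ranking value -log10(p) * sign(log2FC), sorted descending.

    Ties break by larger |log2FC|, then gene ID. Zero p-values are floored
    at the smallest positive double with a warning.
    """
    t = de.table.dropna(subset=["pvalue"]).copy()
    p = t["pvalue"].to_numpy(float)
    if (p == 0).any():
        warnings.warn("zero p-values floored at the smallest positive double")
        p = np.maximum(p, floor if floor is not None else np.finfo(float).tiny)
    val = -np.log10(p) * np.sign(t["log2fc"].to_numpy())
    t["rank_value"] = val
    t["abs_fc"] = t["log2fc"].abs()
    t = t.sort_values(["rank_value", "abs_fc", "gene_id"],
                      ascending=[False, False, True], kind="stable")
    return pd.Series(t["rank_value"].to_numpy(), index=t["gene_id"].to_numpy(),
                     name="rank_value")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def ward2_cluster(z: np.ndarray, k: int) -> np.ndarray:
    """Ward2 agglomerative clustering of rows on Euclidean distance.

    Returns labels in 1..k, deterministic given input order.
    """
    z = np.asarray(z, dtype=float)
    if k < 1 or k > z.shape[0]:
        raise ValueError("k must be between 1 and the number of rows")
    if k == z.shape[0]:
        return np.arange(1, k + 1)
    link = scipy.cluster.hierarchy.linkage(z, method="ward")
    return scipy.cluster.hierarchy.fcluster(link, t=k, criterion="maxclust")


def cluster_signature(z: np.ndarray, genes: list[str], de: DEResult, k: int,
                      diagnostics: dict | None = None) -> GeneClusterSignature:
    """Partition significant genes into k Ward2 clusters with VI directions."""
    labels = ward2_cluster(z, k)
    lfc = de.table.set_index("gene_id")["log2fc"]
    directions = {}
    for c in range(1, k + 1):
        members = [g for g, l in zip(genes, labels) if l == c]
        directions[c] = "up" if lfc.loc[members].mean() >= 0 else "down"
    return GeneClusterSignature(list(genes), labels, k, directions,
                                diagnostics or {})


def consensus_select_k(z: np.ndarray, k_range=range(2, 11), n_subsamples: int = 100,
                       item_fraction: float = 0.8, seed: int = 0,
                       elbow_threshold: float = 0.1,
                       subsample: str = "genes") -> tuple[int, dict]:
    """Choose the number of gene clusters by consensus-clustering stability.

    For each k, genes (rows) are repeatedly subsampled, Ward2-clustered,
    and pairwise co-clustering rates accumulated into a consensus matrix
    normalized by co-sampling counts. The area under the CDF of the
    off-diagonal consensus values (equal to ``1 - mean consensus``)
    quantifies stability; the chosen k is the last one in an unbroken run
    of ks whose area gain over k-1 is at least ``elbow_threshold`` times
    the k=2 area (substantial improvement up to, but not beyond, k).
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    k_range = [k for k in k_range if 2 <= k <= n]
    if not k_range:
        raise ValueError("no feasible k in range")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    areas = {}
    consensus_matrices = {}
    for k in k_range:
        hits = np.zeros((n, n))
        tries = np.zeros((n, n))
        for _ in range(n_subsamples):
            m = max(k + 1, int(round(item_fraction * n)))
            idx = np.sort(rng.choice(n, size=m, replace=False))
            zz = z[idx] if subsample == "genes" else z[idx]
            if subsample == "samples":
                cols = np.sort(rng.choice(z.shape[1],
                                          size=max(2, int(round(item_fraction * z.shape[1]))),
                                          replace=False))
                zz = z[idx][:, cols]
            labels = ward2_cluster(zz, k)
            same = labels[:, None] == labels[None, :]
            tries[np.ix_(idx, idx)] += 1.0
            hits[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(tries > 0, hits / np.maximum(tries, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        vals = cons[iu]
        if np.allclose(vals, vals[0]):
            warnings.warn("degenerate consensus matrix; returning smallest k")
            return k_range[0], {"areas": areas, "consensus": consensus_matrices}
        areas[k] = float(1.0 - vals.mean())  # area under the consensus CDF
        consensus_matrices[k] = cons
    ks = sorted(areas)
    delta = {ks[0]: areas[ks[0]]}
    for a, b in zip(ks, ks[1:]):
        delta[b] = areas[b] - areas[a]
    # stability must improve substantially at every k up to the chosen one
    ref_gain = areas[ks[0]]
    chosen = ks[0]
    for k in ks:
        if delta[k] >= elbow_threshold * ref_gain:
            chosen = k
        else:
            break
    diagnostics = {"areas": areas, "delta_areas": delta, "consensus": consensus_matrices,
                   "elbow_threshold": elbow_threshold}
    return chosen, diagnostics
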