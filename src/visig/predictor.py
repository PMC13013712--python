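"""The 48-gene VI predictor.

Feature selection takes the differentially expressed genes (FDR < 0.01,
VI vs LMP), apportions the 48 slots across the co-expression clusters in
proportion to cluster size (largest-remainder), and picks the best genes
per cluster by p-value. The classifier is a ridge-penalized binomial-logit
GLM on per-gene standardized logCPM, with the penalty chosen by stratified
5-fold inner cross-validation and performance estimated by 100 stratified
70/30 outer splits in which feature selection is repeated inside each
outer training set. The decision threshold is the Youden point on the
training scores.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .countcore import CountMatrix, LogCpmMatrix, filter_genes, log_cpm, with_tmm, zscore_by_gene
from .signature import DEResult, GeneClusterSignature, cluster_signature, grade_design, nb_glm_lrt

__all__ = [
    "PredictorConfig",
    "PredictorModel",
    "CVReport",
    "proportional_select",
    "fit_ridge_logit",
    "inner_cv_lambda",
    "nested_cv_evaluate",
    "train_final",
    "predict_score",
    "reference_adjust",
    "auroc",
    "youden_cutoff",
    "ks_rank_enrichment",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 25)


@dataclass
class PredictorConfig:
    n_genes: int = 48
    n_clusters: int = 4
    fdr: float = 0.01
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    n_outer: int = 100
    outer_test_fraction: float = 0.30
    inner_folds: int = 5
    cpm_threshold: float = 1.0
    min_fraction: float = 0.10


@dataclass
class PredictorModel:
    """Trained ridge binomial-logit predictor on standardized logCPM."""

    gene_ids: list[str]
    means: np.ndarray          # per-gene training mean of logCPM
    sds: np.ndarray            # per-gene training sd (ddof=1)
    coefficients: np.ndarray   # on the standardized scale
    intercept: float
    penalty: float
    youden_cutoff: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate predictor genes")
        if np.any(self.sds <= 0):
            raise ValueError("non-positive standardization sd")

    def to_json(self) -> str:
        return json.dumps({
            "gene_ids": self.gene_ids,
            "means": list(map(float, self.means)),
            "sds": list(map(float, self.sds)),
            "coefficients": list(map(float, self.coefficients)),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "youden_cutoff": self.youden_cutoff,
            "provenance": self.provenance,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PredictorModel":
        d = json.loads(text)
        return cls(d["gene_ids"], np.array(d["means"]), np.array(d["sds"]),
                   np.array(d["coefficients"]), d["intercept"], d["penalty"],
                   d["youden_cutoff"], d.get("provenance", {}))

    def standardized_importance(self) -> pd.Series:
        """Coefficient magnitude on the standardized scale, sorted."""
        s = pd.Series(np.abs(self.coefficients), index=self.gene_ids)
        return s.sort_values(ascending=False)


@dataclass
class CVReport:
    splits: pd.DataFrame   # split, auroc, lambda, n_selected
    selected_genes: list[list[str]]
    mean_auroc: float
    sd_auroc: float


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def proportional_select(de: DEResult, clusters: GeneClusterSignature,
                        n_total: int = 48, fdr: float = 0.01) -> list[str]:
    """Select n_total genes with per-cluster quotas proportional to cluster size.

    Quotas come from largest-remainder apportionment of ``n_total`` by the
    clusters' shares of the significant gene set; within a cluster genes
    are taken in ascending p-value (ties: larger |log2FC|, then gene ID).
    A quota exceeding its cluster's size spills to the cluster with the
    next-largest remainder.
    """
    sig = de.significant(fdr).set_index("gene_id")
    members = {c: [g for g in clusters.cluster_members(c) if g in sig.index]
               for c in range(1, clusters.k + 1)}
    sizes = {c: len(v) for c, v in members.items()}
    m = sum(sizes.values())
    if m < n_total:
        raise ValueError(f"only {m} clustered significant genes; need {n_total}")
    raw = {c: n_total * sizes[c] / m for c in sizes}
    quota = {c: int(np.floor(raw[c])) for c in sizes}
    remainders = sorted(sizes, key=lambda c: (-(raw[c] - quota[c]), c))
    short = n_total - sum(quota.values())
    for c in remainders[:short]:
        quota[c] += 1
    # spill quotas that exceed cluster size
    for c in sorted(quota, key=lambda c: (-(raw[c] - int(np.floor(raw[c]))), c)):
        while quota[c] > sizes[c]:
            quota[c] -= 1
            for d in remainders:
                if quota[d] < sizes[d] and d != c:
                    warnings.warn(f"cluster {c} quota spilled to cluster {d}")
                    quota[d] += 1
                    break
    selected: list[str] = []
    for c, genes in members.items():
        tab = sig.loc[genes]
        tab = tab.assign(abs_fc=tab["log2fc"].abs(), gene=tab.index)
        tab = tab.sort_values(["pvalue", "abs_fc", "gene"],
                              ascending=[True, False, True], kind="stable")
        selected.extend(tab.index[: quota[c]].tolist())
    assert len(selected) == n_total
    return selected


# ---------------------------------------------------------------------------
# Ridge binomial logit
# ---------------------------------------------------------------------------

def _ridge_logit_objective(beta: np.ndarray, b0: float, X: np.ndarray,
                           y: np.ndarray, lam: float) -> float:
    eta = b0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return nll + 0.5 * lam * beta @ beta


def fit_ridge_logit(X: np.ndarray, y: np.ndarray, lam: float,
                    max_iter: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Ridge-penalized logistic regression by damped Newton (IRLS).

    Minimizes ``-(1/n) Bernoulli log-likelihood + (lam/2) ||beta||^2`` with
    an unpenalized intercept, to gradient norm < ``tol``. Deterministic.
    Returns (coefficients, intercept).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    pen = np.full(p + 1, lam)
    pen[0] = 0.0
    theta = np.zeros(p + 1)
    theta[0] = scipy.special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    obj = _ridge_logit_objective(theta[1:], theta[0], X, y, lam)

    def _check_separation(th):
        # at lambda = 0 a separating direction sends the MLE to infinity
        if lam > 0 or np.abs(th[1:]).max() < 10.0:
            return
        eta = Xa @ th
        if eta[y == 1].min() > eta[y == 0].max():
            raise RuntimeError("no finite optimum at lambda = 0 (separation); "
                               "use lambda > 0")

    for it in range(max_iter):
        eta = Xa @ theta
        mu = scipy.special.expit(eta)
        grad = Xa.T @ (mu - y) / n + pen * theta
        if np.linalg.norm(grad) < tol:
            _check_separation(theta)
            return theta[1:], float(theta[0])
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (Xa.T * w) @ Xa / n + np.diag(pen)
        step = np.linalg.solve(H + 1e-12 * np.eye(p + 1), grad)
        t = 1.0
        for _ in range(50):
            cand = theta - t * step
            new = _ridge_logit_objective(cand[1:], cand[0], X, y, lam)
            if new <= obj - 1e-4 * t * (grad @ step) or t < 1e-8:
                break
            t *= 0.5
        theta, obj = cand, new
    eta = Xa @ theta
    mu = scipy.special.expit(eta)
    grad = Xa.T @ (mu - y) / n + pen * theta
    _check_separation(theta)
    if lam == 0 and np.linalg.norm(grad) >= max(tol, 1e-6):
        raise RuntimeError("no finite optimum at lambda = 0 (separation?); "
                           "use lambda > 0")
    if np.linalg.norm(grad) >= max(tol, 1e-6):
        warnings.warn("ridge logit stopped before reaching gradient tolerance")
    return theta[1:], float(theta[0])


def _predict_proba(X: np.ndarray, beta: np.ndarray, b0: float) -> np.ndarray:
    return scipy.special.expit(b0 + X @ beta)


def inner_cv_lambda(X: np.ndarray, y: np.ndarray,
                    lambda_grid=DEFAULT_LAMBDA_GRID, k: int = 5,
                    seed: int = 0) -> float:
    """Pick the ridge penalty by stratified k-fold inner CV on AUROC.

    Ties go to the larger (more conservative) penalty.
    """
    y = np.asarray(y, float)
    k = min(k, int(min(y.sum(), len(y) - y.sum())))
    if k < 2:
        raise ValueError("too few minority-class samples for inner CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    grid = np.sort(np.asarray(lambda_grid, float))
    aucs = np.zeros(len(grid))
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        for i, lam in enumerate(grid):
            beta, b0 = fit_ridge_logit(Xtr, y[tr], lam)
            aucs[i] += _auroc_stat(_predict_proba(Xte, beta, b0), y[te])
    best = np.flatnonzero(aucs == aucs.max())[-1]  # ties -> larger lambda
    return float(grid[best])


# ---------------------------------------------------------------------------
# Performance statistics
# ---------------------------------------------------------------------------

def _auroc_stat(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the Mann–Whitney statistic; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auroc(scores, labels, n_boot: int = 2000, seed: int = 0,
          level: float = 0.95) -> dict:
    """AUROC with class-stratified bootstrap CI and a rank-sum p-value.

    The point estimate is the Mann–Whitney U statistic scaled to [0, 1]
    (ties one half); the CI is the percentile interval over ``n_boot``
    bootstrap resamples drawn within each class; the p-value is the
    two-sided normal-approximation Wilcoxon rank-sum test with tie
    correction.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    est = _auroc_stat(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boots[b] = _auroc_stat(np.concatenate([bp, bn]),
                               np.concatenate([np.ones(len(bp)), np.zeros(len(bn))]))
    alpha = 1.0 - level
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    p = scipy.stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                 method="asymptotic").pvalue
    return {"auroc": est, "ci": (float(lo), float(hi)), "pvalue": float(p)}


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints of adjacent distinct score values
    (plus outer sentinels); ties in J go to the lowest cutoff, favoring
    sensitivity. Positivity downstream is score > cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids])
    n1 = labels.sum()
    n0 = len(labels) - n1
    best_j, best_c = -np.inf, cands[0]
    for c in cands:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def ks_rank_enrichment(ranked_gene_ids, subset) -> tuple[float, float]:
    """Two-sample KS test of subset rank positions against the complement.

    Detects whether the genes of ``subset`` sit unusually high or low in a
    ranked list. Exact p for small samples, asymptotic otherwise.
    """
    ranked = list(ranked_gene_ids)
    sub = set(subset)
    if not sub:
        raise ValueError("empty subset")
    if not sub < set(ranked):
        raise ValueError("subset must be a strict subset of the ranked list")
    pos = np.arange(1, len(ranked) + 1, dtype=float)
    in_sub = np.array([g in sub for g in ranked])
    res = scipy.stats.ks_2samp(pos[in_sub], pos[~in_sub], alternative="two-sided",
                               method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Nested cross-validation and final training
# ---------------------------------------------------------------------------

def _derive_features(cm_train: CountMatrix, meta_train: pd.DataFrame,
                     config: PredictorConfig) -> tuple[list[str], DEResult]:
    """DE + clustering + proportional selection on training data only."""
    cmf = filter_genes(cm_train, config.cpm_threshold, config.min_fraction)
    cmf = with_tmm(cmf)
    de = nb_glm_lrt(cmf, grade_design(meta_train), contrast="VI")
    sig = de.significant(config.fdr)
    if len(sig) < config.n_genes:
        # too few significant genes (e.g. permuted labels): fall back to top-p
        warnings.warn("fewer significant genes than predictor slots; using top p-values")
        tab = de.table.dropna(subset=["pvalue"]).sort_values(
            ["pvalue", "gene_id"], kind="stable")
        return tab["gene_id"].head(config.n_genes).tolist(), de
    lcm = log_cpm(cmf)
    sig_genes = sig["gene_id"].tolist()
    z = zscore_by_gene(lcm.subset_genes(sig_genes))
    k = min(config.n_clusters, len(sig_genes))
    clusters = cluster_signature(z, sig_genes, de, k)
    return proportional_select(de, clusters, config.n_genes, config.fdr), de


def _training_matrix(cm: CountMatrix, genes: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lcm = log_cpm(with_tmm(cm))
    sub = lcm.subset_genes(genes)
    X = sub.values.T  # samples x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return X, mu, sd


def fit_outer_split(cm: CountMatrix, meta: pd.DataFrame, train_idx,
                    config: PredictorConfig, seed: int = 0):
    """Derive features and fit the ridge model using training samples only.

    Everything — expression filter, TMM, DE, clustering, the 48-gene
    selection, standardization, the inner-CV penalty and the fit — is
    computed from ``train_idx``; samples outside it are never touched,
    which is the leakage guarantee of the outer loop.
    """
    train_idx = np.asarray(train_idx)
    meta_tr = meta.iloc[train_idx].reset_index(drop=True)
    cm_tr = cm.subset_samples(train_idx)
    genes, _ = _derive_features(cm_tr, meta_tr, config)
    X, mu, sd = _training_matrix(cm_tr, genes)
    Xs = (X - mu) / sd
    y_tr = meta_tr["vi"].to_numpy(float)
    lam = inner_cv_lambda(Xs, y_tr, config.lambda_grid, config.inner_folds, seed=seed)
    beta, b0 = fit_ridge_logit(Xs, y_tr, lam)
    return genes, beta, b0, mu, sd, lam


def nested_cv_evaluate(cm: CountMatrix, meta: pd.DataFrame,
                       config: PredictorConfig | None = None,
                       seed: int = 0) -> CVReport:
    """Estimate predictor performance by repeated stratified 70/30 splits.

    In every outer split, gene filtering, TMM, differential expression,
    clustering and the 48-gene proportional selection are re-derived on the
    outer training set alone; the ridge penalty comes from stratified
    5-fold inner CV; performance is the AUROC for VI vs non-VI on the
    untouched outer test set.
    """
    config = config or PredictorConfig()
    y = meta["vi"].to_numpy(float)
    sss = StratifiedShuffleSplit(n_splits=config.n_outer,
                                 test_size=config.outer_test_fraction,
                                 random_state=seed)
    rows, gene_lists = [], []
    for s, (tr, te) in enumerate(sss.split(np.zeros(len(y)), y)):
        meta_tr = meta.iloc[tr].reset_index(drop=True)
        if len(set(meta_tr["grade"])) < 3:
            warnings.warn(f"outer split {s} lacks a grade; skipped")
            continue
        genes, beta, b0, mu, sd, lam = fit_outer_split(cm, meta, tr, config,
                                                       seed=seed + 1000 + s)
        cm_te = cm.subset_samples(te)
        lcm_te = log_cpm(with_tmm(cm_te)) if len(te) > 1 else log_cpm(cm_te)
        Xte = (lcm_te.subset_genes(genes).values.T - mu) / sd
        rows.append({"split": s, "auroc": _auroc_stat(_predict_proba(Xte, beta, b0), y[te]),
                     "lambda": lam, "n_selected": len(genes)})
        gene_lists.append(genes)
    splits = pd.DataFrame(rows)
    return CVReport(splits, gene_lists,
                    float(splits["auroc"].mean()), float(splits["auroc"].std(ddof=1)))


def train_final(cm: CountMatrix, meta: pd.DataFrame,
                config: PredictorConfig | None = None, seed: int = 0) -> PredictorModel:
    """Train the final 48-gene predictor on the full discovery cohort.

    Stores the per-gene standardization parameters and the Youden cutoff
    computed on the training scores.
    """
    config = config or PredictorConfig()
    y = meta["vi"].to_numpy(float)
    genes, de = _derive_features(cm, meta, config)
    X, mu, sd = _training_matrix(cm, genes)
    Xs = (X - mu) / sd
    lam = inner_cv_lambda(Xs, y, config.lambda_grid, config.inner_folds, seed=seed)
    beta, b0 = fit_ridge_logit(Xs, y, lam)
    train_scores = _predict_proba(Xs, beta, b0)
    cutoff = youden_cutoff(train_scores, y)
    prov = {"seed": seed,
            "training_hash": hashlib.sha1(cm.counts.tobytes()).hexdigest()[:12],
            "n_samples": int(len(y))}
    return PredictorModel(list(genes), mu, sd, beta, b0, lam, cutoff, prov)


def predict_score(model: PredictorModel, lcm: LogCpmMatrix,
                  impute_missing: bool = False) -> pd.DataFrame:
    """Apply the trained predictor to a logCPM matrix; returns unit scores."""
    have = set(lcm.gene_ids)
    missing = [g for g in model.gene_ids if g not in have]
    if missing and not impute_missing:
        raise ValueError(f"{len(missing)} predictor gene(s) missing; "
                         "pass impute_missing=True to use training means")
    if missing:
        warnings.warn(f"imputing {len(missing)} missing gene(s) at training means")
    pos = {g: i for i, g in enumerate(lcm.gene_ids)}
    X = np.empty((len(lcm.sample_ids), len(model.gene_ids)))
    for j, g in enumerate(model.gene_ids):
        X[:, j] = lcm.values[pos[g]] if g in pos else model.means[j]
    Xs = (X - model.means) / model.sds
    probs = _predict_proba(Xs, model.coefficients, model.intercept)
    return pd.DataFrame({"unit_id": lcm.sample_ids, "score": "vi_probability",
                         "value": probs})


def reference_adjust(target_lcm: LogCpmMatrix, reference_lcm: LogCpmMatrix) -> LogCpmMatrix:
    """Match each target gene's logCPM mean and variance to the reference cohort.

    Per gene: x' = (x - m_t)/s_t * s_r + m_r. The reference is never
    altered; genes outside the shared universe are dropped with a warning;
    a zero-variance target gene is shifted only.
    """
    shared = [g for g in target_lcm.gene_ids if g in set(reference_lcm.gene_ids)]
    lost = len(target_lcm.gene_ids) - len(shared)
    if lost:
        warnings.warn(f"{lost} target gene(s) outside the shared universe dropped")
    t = target_lcm.subset_genes(shared)
    r = reference_lcm.subset_genes(shared)
    mt = t.values.mean(axis=1, keepdims=True)
    st = t.values.std(axis=1, ddof=1, keepdims=True)
    mr = r.values.mean(axis=1, keepdims=True)
    sr = r.values.std(axis=1, ddof=1, keepdims=True)
    flat = st[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance target gene(s) shifted only")
    st[flat] = 1.0
    sr[flat] = 1.0
    adj = (t.values - mt) / st * sr + mr
    return LogCpmMatrix(t.gene_ids, t.sample_ids, adj, t.prior_count, t.source)
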