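"""Diagnostic accuracy: confusion counts, exact intervals, Bayesian PPV/NPV.

Applying the prespecified Youden cutoff to a validation cohort gives
confusion counts; sensitivity and specificity carry Clopper–Pearson exact
intervals and, under uniform Beta(1,1) priors, conjugate Beta posteriors
Beta(1+TP, 1+FN) and Beta(1+TN, 1+FP). Monte-Carlo draws from those
posteriors are pushed through Bayes' theorem to project PPV and NPV across
an assumed disease-prevalence range, reported as posterior medians with
2.5th–97.5th percentile credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "DxCounts",
    "DxPosterior",
    "confusion",
    "clopper_pearson",
    "beta_posteriors",
    "project_ppv_npv",
]

DEFAULT_PREVALENCES = (0.15, 0.20, 0.25, 0.30, 0.35)


@dataclass(frozen=True)
class DxCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class DxPosterior:
    """Beta posterior parameters for sensitivity and specificity."""

    alpha_se: float
    beta_se: float
    alpha_sp: float
    beta_sp: float


def confusion(scores, labels, cutoff: float) -> DxCounts:
    """Confusion counts at a cutoff; positivity is strictly score > cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = scores > cutoff
    return DxCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k/n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(scipy.stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(scipy.stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def beta_posteriors(counts: DxCounts) -> DxPosterior:
    """Conjugate Beta posteriors for sensitivity/specificity, Beta(1,1) prior."""
    return DxPosterior(1.0 + counts.tp, 1.0 + counts.fn,
                       1.0 + counts.tn, 1.0 + counts.fp)


def project_ppv_npv(post: DxPosterior, prevalences=DEFAULT_PREVALENCES,
                    n_draws: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo projection of PPV/NPV over assumed prevalence.

    Draws paired (sensitivity, specificity) samples from the posteriors
    and applies Bayes' theorem at each prevalence; returns the median and
    2.5th/97.5th percentiles (linear-interpolation quantiles) per
    prevalence and quantity.
    """
    prevalences = np.atleast_1d(np.asarray(prevalences, float))
    if np.any((prevalences <= 0) | (prevalences >= 1)):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    if n_draws < 1000:
        raise ValueError("need at least 1000 draws")
    rng = np.random.default_rng(seed)
    se = rng.beta(post.alpha_se, post.beta_se, size=n_draws)
    sp = rng.beta(post.alpha_sp, post.beta_sp, size=n_draws)
    rows = []
    for p in prevalences:
        ppv = se * p / (se * p + (1.0 - sp) * (1.0 - p))
        npv = sp * (1.0 - p) / ((1.0 - se) * p + sp * (1.0 - p))
        for name, v in (("ppv", ppv), ("npv", npv)):
            lo, med, hi = np.quantile(v, [0.025, 0.5, 0.975])
            rows.append({"prevalence": float(p), "quantity": name,
                         "median": float(med), "lo": float(lo), "hi": float(hi)})
    out = pd.DataFrame(rows)
    out.attrs["n_draws"] = n_draws
    out.attrs["seed"] = seed
    return out
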