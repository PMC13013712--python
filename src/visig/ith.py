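"""Intra- vs inter-tumor heterogeneity of predictor scores.

Multi-region tumors are down-sampled to two regions each; the absolute
score difference within a tumor (intra pair) is compared against the same
number of differences between random regions of two different tumors
(inter pairs) with a rank-sum test. Region-pair agreement is summarized by
a Spearman correlation, and the preranked GSEA here asks whether a gene
set (the 48 predictor genes) is enriched among genes with the most
region-reproducible expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "sample_region_pairs",
    "intra_inter_test",
    "region_pair_correlation",
    "preranked_gsea",
]


def sample_region_pairs(scores: pd.DataFrame, seed: int = 0,
                        score_col: str = "score") -> pd.DataFrame:
    """Sample matched intra- and inter-tumor region pairs.

    One intra pair per tumor (two regions drawn without replacement), and
    an equal number of inter pairs, each drawn as two distinct tumors with
    one random region apiece; tumors are sampled without replacement
    within a draw and with replacement across draws. Tumors with a single
    region are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    groups = scores.groupby("tumor_id", sort=True)
    multi = {t: g for t, g in groups if len(g) >= 2}
    dropped = len(groups) - len(multi)
    if dropped:
        warnings.warn(f"{dropped} tumor(s) with a single region excluded")
    if len(multi) < 2:
        raise ValueError("need at least 2 tumors with >= 2 regions")
    rows = []
    tumors = sorted(multi)
    for t in tumors:
        g = multi[t]
        i, j = rng.choice(len(g), size=2, replace=False)
        rows.append({"tumor_id": t, "region_a": g.iloc[i]["region_id"],
                     "region_b": g.iloc[j]["region_id"],
                     "score_a": g.iloc[i][score_col], "score_b": g.iloc[j][score_col],
                     "pair_type": "intra"})
    for _ in range(len(tumors)):
        ta, tb = rng.choice(len(tumors), size=2, replace=False)
        ga, gb = multi[tumors[ta]], multi[tumors[tb]]
        ra = ga.iloc[rng.integers(len(ga))]
        rb = gb.iloc[rng.integers(len(gb))]
        rows.append({"tumor_id": f"{tumors[ta]}|{tumors[tb]}",
                     "region_a": ra["region_id"], "region_b": rb["region_id"],
                     "score_a": ra[score_col], "score_b": rb[score_col],
                     "pair_type": "inter"})
    return pd.DataFrame(rows)


def intra_inter_test(pairs: pd.DataFrame) -> dict:
    """Compare |score difference| between intra and inter pairs (rank-sum)."""
    d = (pairs["score_a"] - pairs["score_b"]).abs()
    intra = d[pairs["pair_type"] == "intra"].to_numpy()
    inter = d[pairs["pair_type"] == "inter"].to_numpy()
    if len(intra) == 0 or len(inter) == 0:
        raise ValueError("both pair types must be present")
    if np.all(intra == intra[0]) and np.all(inter == intra[0]):
        p = 1.0
    else:
        p = float(scipy.stats.mannwhitneyu(intra, inter,
                                           alternative="two-sided").pvalue)
    return {"median_intra": float(np.median(intra)),
            "median_inter": float(np.median(inter)),
            "pvalue": p}


def region_pair_correlation(pairs: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of intra-pair region scores (score_a vs score_b)."""
    intra = pairs[pairs["pair_type"] == "intra"]
    if len(intra) < 3:
        raise ValueError("need at least 3 intra pairs")
    a = intra["score_a"].to_numpy(float)
    b = intra["score_b"].to_numpy(float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant scores: Spearman undefined")
    res = scipy.stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def _weighted_ks_es(in_set: np.ndarray, values: np.ndarray, weight_p: float) -> float:
    """Enrichment score: extremum of the weighted KS-like running sum."""
    n = len(in_set)
    nh = int(in_set.sum())
    w = np.abs(values) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit = in_set / nh
    else:
        hit = hit_w / denom
    miss = np.where(~in_set, 1.0 / (n - nh), 0.0)
    running = np.cumsum(hit - miss)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranked_values: pd.Series, gene_set, weight_p: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> dict:
    """Preranked GSEA with the weighted KS-like running-sum statistic.

    ``ranked_values`` maps gene -> ranking value; genes are walked in
    descending value order, the running sum gaining |value|^weight_p
    (normalized) at set genes and losing 1/(N - |set|) elsewhere. The
    enrichment score (ES) is the extremum; the null comes from set-label
    permutations; NES divides ES by the mean |null ES| of the same sign;
    the p-value is the two-sided permutation tail.
    """
    vals = ranked_values.sort_values(ascending=False, kind="stable")
    genes = vals.index.to_numpy(object)
    v = vals.to_numpy(float)
    if np.all(v == 0):
        raise ValueError("all ranking values are zero")
    sub = set(gene_set) & set(genes)
    if not sub or len(sub) >= len(genes):
        raise ValueError("gene set must be a nonempty strict subset of the universe")
    in_set = np.array([g in sub for g in genes])
    es = _weighted_ks_es(in_set, v, weight_p)
    rng = np.random.default_rng(seed)
    nh = int(in_set.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=nh, replace=False)] = True
        null[b] = _weighted_ks_es(perm, v, weight_p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
    nes = es / denom if denom > 0 else np.nan
    p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
    return {"es": es, "nes": float(nes), "pvalue": float(p), "n_set": nh}


def gene_region_correlations(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                             method: str = "spearman") -> pd.Series:
    """Per-gene correlation of expression across matched region pairs.

    ``expr_a`` and ``expr_b`` are gene x tumor matrices holding the two
    down-sampled regions of each tumor; the result ranks genes by how
    reproducible their expression is between regions.
    """
    if not expr_a.index.equals(expr_b.index) or expr_a.shape != expr_b.shape:
        raise ValueError("matrices must share genes and shape")
    a = expr_a.to_numpy(float)
    b = expr_b.to_numpy(float)
    if method == "spearman":
        a = np.apply_along_axis(scipy.stats.rankdata, 1, a)
        b = np.apply_along_axis(scipy.stats.rankdata, 1, b)
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, (am * bm).sum(axis=1) / denom, np.nan)
    return pd.Series(r, index=expr_a.index, name="region_correlation")
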