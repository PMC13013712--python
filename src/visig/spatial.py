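"""Spot-level spatial procedures: QC, pseudo-bulk, local correlation, distance bins.

Spots are lattice points with center coordinates in micrometres, one
pathology annotation each, a detected-gene count used for QC, and any
number of score or count columns. The local-correlation statistic is a
kernel-weighted Spearman computed in a moving window around each spot,
averaged over the tissue to one number per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "SpotSample",
    "filter_spots",
    "pseudo_bulk",
    "sw_correlation",
    "distance_bins",
]


@dataclass
class SpotSample:
    """One spatial sample: spot table plus optional spot x gene counts."""

    spots: pd.DataFrame  # spot_id, x_um, y_um, annotation, n_genes_detected, score cols
    spacing_um: float = 100.0
    diameter_um: float = 50.0
    counts: pd.DataFrame | None = field(default=None, repr=False)  # spot x gene

    def __post_init__(self) -> None:
        req = {"spot_id", "x_um", "y_um", "annotation"}
        missing = req - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.spots[["x_um", "y_um"]].to_numpy(float))):
            raise ValueError("spot coordinates must be finite")

    @property
    def n_spots(self) -> int:
        return len(self.spots)


def filter_spots(s: SpotSample, min_genes: int = 250) -> SpotSample:
    """Drop low-quality spots with fewer than ``min_genes`` detected genes."""
    if "n_genes_detected" not in s.spots.columns:
        raise ValueError("spot table has no n_genes_detected column")
    keep = s.spots["n_genes_detected"].to_numpy() >= min_genes
    if not keep.any():
        raise ValueError("spot QC removed every spot")
    spots = s.spots.loc[keep].reset_index(drop=True)
    counts = s.counts.loc[keep.nonzero()[0]].reset_index(drop=True) if s.counts is not None else None
    if counts is not None:
        counts.index = spots.index
    return SpotSample(spots, s.spacing_um, s.diameter_um, counts)


def pseudo_bulk(s: SpotSample) -> pd.Series:
    """Per-gene counts summed over all retained spots."""
    if s.counts is None:
        raise ValueError("pseudo_bulk requires count mode")
    return s.counts.sum(axis=0)


def _kernel_weights(d: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    if kernel == "bisquare":
        w = np.where(d < bandwidth, (1.0 - (d / bandwidth) ** 2) ** 2, 0.0)
    elif kernel == "gaussian":
        w = np.exp(-0.5 * (d / bandwidth) ** 2)
    elif kernel == "uniform":
        w = (d <= bandwidth).astype(float)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return w


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    vx = np.sum(w * (x - mx) ** 2) / sw
    vy = np.sum(w * (y - my) ** 2) / sw
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(np.sum(w * (x - mx) * (y - my)) / sw / np.sqrt(vx * vy))


def sw_correlation(s: SpotSample, score_a: str, score_b: str,
                   bandwidth: float = 5.0, kernel: str = "bisquare",
                   method: str = "spearman") -> tuple[pd.Series, float]:
    """Spatially weighted local correlation of two spot-level scores.

    For the spearman method both scores are globally rank-transformed
    first; each spot then gets a kernel-weighted Pearson correlation over
    its neighborhood. ``bandwidth`` is in lattice units (multiples of the
    spot spacing). Returns the per-spot local coefficients and their mean
    over the sample; spots with fewer than 2 in-range neighbors or zero
    local variance are skipped with a warning.
    """
    x = s.spots[score_a].to_numpy(float)
    y = s.spots[score_b].to_numpy(float)
    if method == "spearman":
        x = scipy.stats.rankdata(x)
        y = scipy.stats.rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    xy = s.spots[["x_um", "y_um"]].to_numpy(float)
    bw_um = bandwidth * s.spacing_um
    local = np.full(len(x), np.nan)
    n_skipped = 0
    for i in range(len(x)):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        w = _kernel_weights(d, bw_um, kernel)
        if (w > 0).sum() < 2:
            n_skipped += 1
            continue
        r = _weighted_corr(x[w > 0], y[w > 0], w[w > 0])
        if np.isnan(r):
            n_skipped += 1
        else:
            local[i] = r
    if n_skipped:
        warnings.warn(f"{n_skipped} spot(s) skipped (too few neighbors or zero local variance)")
    valid = np.isfinite(local)
    if not valid.any():
        raise ValueError("no spot admitted a local correlation")
    mean_rho = float(local[valid].mean())
    return pd.Series(local, index=s.spots["spot_id"].to_numpy(), name="local_rho"), mean_rho


def distance_bins(s: SpotSample, focus_label: str = "VI focus",
                  threshold_um: float = 1000.0) -> pd.Series:
    """Bin spots as proximal/distal to annotated invaded-vessel foci.

    Focus-labeled spots are proximal; other spots are proximal iff their
    center lies within ``threshold_um`` (inclusive) of any focus spot. A
    sample without focus spots is entirely distal.
    """
    ann = s.spots["annotation"].to_numpy()
    xy = s.spots[["x_um", "y_um"]].to_numpy(float)
    is_focus = ann == focus_label
    out = np.full(len(ann), "distal", dtype=object)
    if is_focus.any():
        fxy = xy[is_focus]
        d = np.sqrt(((xy[:, None, :] - fxy[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        out[(d <= threshold_um) | is_focus] = "proximal"
    return pd.Series(out, index=s.spots["spot_id"].to_numpy(), name="bin")
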