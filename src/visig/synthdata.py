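"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of the study cohorts:

* bulk RNA-seq counts with a three-level tumor-grade factor (LMP < NST < VI)
  and four planted co-expressed gene clusters (defaults 115/37/182/140 genes,
  three up-regulated in VI and one down-regulated), negative-binomial noise,
  log-normal library sizes, and optional additive log-scale batch shifts;
* multi-region tumors whose region scores are a tumor-level latent value
  plus region-level noise (tumor signal >> region noise);
* spot lattices with pathology annotations including invaded-vessel foci;
* paired biopsy/resection scores with an attenuated correlation.

Every generator is deterministic given its seed, and each returns a truth
table for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countcore import CountMatrix
from .spatial import SpotSample

GRADES = ("LMP", "NST", "VI")

__all__ = [
    "CohortConfig",
    "TruthTable",
    "SpotConfig",
    "generate_bulk_cohort",
    "generate_multiregion_cohort",
    "generate_spot_sample",
    "generate_biopsy_pairs",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic bulk discovery/validation cohort.

    The defaults mirror the discovery design: ~100 stage I tumors with VI
    present in 30%, four planted clusters of sizes 115/37/182/140 (474
    signature genes), three clusters up in VI and one down, and NST tumors
    carrying half the VI effect so the heatmap gradient LMP < NST < VI holds.
    """

    n_samples: int = 100
    grade_fractions: tuple[float, float, float] = (0.35, 0.35, 0.30)  # LMP, NST, VI
    n_genes: int = 2000
    cluster_sizes: tuple[int, ...] = (115, 37, 182, 140)
    cluster_log2fc: tuple[float, ...] = (1.5, 2.0, 1.2, -1.5)
    nst_effect_scale: float = 0.5
    dispersion: float = 0.15
    libsize_log_mean: float = 16.1  # ln scale; e^16.1 ~ 1e7 reads
    libsize_log_sd: float = 0.3
    batch_shift_sd: float = 0.0
    n_batches: int = 1
    cluster_activity_sd: float = 0.8  # per-sample shared within-cluster factor (log2)
    cluster_activity_corr: float = 0.8  # correlation of cluster 1 and 3 activities
    low_expr_fraction: float = 0.05  # genes planted below the CPM filter
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_samples) != self.n_samples or self.n_samples < 6:
            raise ValueError("n_samples must be an integer >= 6")
        if int(self.n_genes) != self.n_genes or self.n_genes <= 0:
            raise ValueError("n_genes must be a positive integer")
        if abs(sum(self.grade_fractions) - 1.0) > 1e-8:
            raise ValueError("grade_fractions must sum to 1")
        if len(self.cluster_sizes) != 4 or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("need 4 cluster sizes, each >= 1")
        if sum(self.cluster_sizes) >= self.n_genes:
            raise ValueError("cluster sizes must sum to < n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.batch_shift_sd < 0 or self.n_batches < 1:
            raise ValueError("invalid batch parameters")
        if not 0 <= self.nst_effect_scale <= 1:
            raise ValueError("nst_effect_scale must be in [0, 1]")
        if any(_grade_counts(self)[g] < 2 for g in GRADES):
            raise ValueError("each grade needs at least 2 samples")


def _grade_counts(config: CohortConfig) -> dict[str, int]:
    """Largest-remainder apportionment of samples to the three grades."""
    n = config.n_samples
    raw = np.array(config.grade_fractions) * n
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(-rem)[: n - base.sum()]:
        base[i] += 1
    return dict(zip(GRADES, base.tolist()))


@dataclass
class TruthTable:
    """Ground truth of a simulated bulk cohort."""

    cluster_genes: dict[int, list[str]]  # 1-based cluster -> gene ids
    true_log2fc: pd.Series               # per gene, VI vs LMP
    grades: pd.Series                    # per sample
    batches: pd.Series                   # per sample

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for genes in self.cluster_genes.values():
            dup = seen & set(genes)
            if dup:
                raise ValueError(f"genes in more than one cluster: {sorted(dup)[:3]}")
            seen |= set(genes)

    @property
    def planted_genes(self) -> list[str]:
        return [g for genes in self.cluster_genes.values() for g in genes]


def generate_bulk_cohort(config: CohortConfig) -> tuple[CountMatrix, pd.DataFrame, TruthTable]:
    """Simulate a bulk RNA-seq cohort with planted VI signature clusters.

    Counts are negative binomial (Var = mu + phi * mu^2) around per-gene
    baselines, with the VI-vs-LMP log2 fold change applied in full to VI
    samples and scaled by ``nst_effect_scale`` in NST samples. Each cluster
    additionally carries a per-sample latent activity shared by its member
    genes, which is what makes the four clusters distinct co-expression
    modules rather than interchangeable DE gene sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples

    counts_per_grade = _grade_counts(config)
    grades = np.repeat(GRADES, [counts_per_grade[g] for g in GRADES])
    grades = rng.permutation(grades)
    grade_mult = np.select(
        [grades == "LMP", grades == "NST", grades == "VI"],
        [0.0, config.nst_effect_scale, 1.0],
    )

    gene_ids = np.array([f"g{i:05d}" for i in range(G)], dtype=object)
    # baseline relative abundance, log2 CPM-like scale
    base = rng.normal(5.0, 2.0, size=G)
    n_low = int(round(config.low_expr_fraction * G))
    k = sum(config.cluster_sizes)
    # planted genes: comfortably expressed so they survive the CPM filter
    planted_idx = np.arange(k)
    base[planted_idx] = np.clip(rng.normal(5.0, 1.5, size=k), 3.0, None)
    if n_low:
        low_idx = rng.choice(np.arange(k, G), size=min(n_low, G - k), replace=False)
        base[low_idx] = rng.uniform(-4.0, -2.0, size=len(low_idx))

    true_lfc = np.zeros(G)
    cluster_genes: dict[int, list[str]] = {}
    start = 0
    cluster_of = np.full(G, 0)
    for c, (size, lfc) in enumerate(zip(config.cluster_sizes, config.cluster_log2fc), start=1):
        idx = np.arange(start, start + size)
        true_lfc[idx] = lfc
        cluster_of[idx] = c
        cluster_genes[c] = gene_ids[idx].tolist()
        start += size

    log2mu = base[:, None] + true_lfc[:, None] * grade_mult[None, :]
    # shared within-cluster activity: per (cluster, sample) latent factor
    if config.cluster_activity_sd > 0:
        activity = rng.normal(0.0, 1.0, size=(4, S))
        # clusters 1 and 3 are transcriptionally related (overlapping programs):
        # their activities are correlated, so they are each other's nearest clusters
        rho = config.cluster_activity_corr
        activity[2] = rho * activity[0] + np.sqrt(max(1.0 - rho**2, 0.0)) * activity[2]
        activity *= config.cluster_activity_sd
        loading = rng.normal(1.0, 0.2, size=G)
        for c in range(1, 5):
            members = cluster_of == c
            log2mu[members] += loading[members, None] * activity[c - 1][None, :]

    batches = rng.integers(0, config.n_batches, size=S)
    if config.batch_shift_sd > 0 and config.n_batches > 1:
        shift = rng.normal(0.0, config.batch_shift_sd, size=(G, config.n_batches))
        log2mu += shift[:, batches]

    lib = np.exp(rng.normal(config.libsize_log_mean, config.libsize_log_sd, size=S))
    rel = 2.0 ** log2mu
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    phi = config.dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam).astype(np.int64)

    sample_ids = np.array([f"s{j:03d}" for j in range(S)], dtype=object)
    cm = CountMatrix(gene_ids, sample_ids, counts)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "grade": grades,
        "vi": (grades == "VI").astype(int),
        "batch": batches,
        "tumor_id": sample_ids,
        "region_id": "R1",
    })
    truth = TruthTable(
        cluster_genes=cluster_genes,
        true_log2fc=pd.Series(true_lfc, index=gene_ids),
        grades=pd.Series(grades, index=sample_ids),
        batches=pd.Series(batches, index=sample_ids),
    )
    return cm, meta, truth


def generate_multiregion_cohort(n_tumors: int = 63, regions_per_tumor: int = 2,
                                tumor_effect_sd: float = 1.0,
                                region_noise_sd: float = 0.2,
                                seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate multi-region predictor scores: tumor latent + region noise.

    Emulates a multi-region cohort in which the tumor-level signal dominates
    region-level variability, the regime where a transcriptional predictor
    is robust to intra-tumor heterogeneity.
    """
    if n_tumors < 2:
        raise ValueError("need at least 2 tumors")
    if regions_per_tumor < 2:
        raise ValueError("need at least 2 regions per tumor")
    if tumor_effect_sd < 0 or region_noise_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, tumor_effect_sd, size=n_tumors)
    noise = rng.normal(0.0, region_noise_sd, size=(n_tumors, regions_per_tumor))
    rows = []
    for t in range(n_tumors):
        for r in range(regions_per_tumor):
            rows.append({
                "tumor_id": f"T{t:03d}",
                "region_id": f"R{r + 1}",
                "score": latent[t] + noise[t, r],
            })
    scores = pd.DataFrame(rows)
    truth = {"tumor_latent": latent, "region_noise": noise}
    return scores, truth


@dataclass
class SpotConfig:
    """Layout of a synthetic spot lattice.

    ``region_layout`` maps an annotation label to a list of half-open
    lattice blocks ``(row0, row1, col0, col1)``; later labels overwrite
    earlier ones and uncovered spots fall back to ``background_label``.
    ``region_score_means`` gives each label's mean for every score column.
    """

    grid_rows: int = 20
    grid_cols: int = 20
    spot_spacing_um: float = 100.0
    spot_diameter_um: float = 50.0
    region_layout: dict[str, list[tuple[int, int, int, int]]] = field(
        default_factory=lambda: {
            "tumor": [(0, 20, 0, 10)],
            "desmoplastic stroma": [(0, 20, 10, 14)],
            "VI focus": [(8, 12, 14, 17)],
        })
    background_label: str = "normal"
    region_score_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "normal": {"vi_score": 0.0},
            "tumor": {"vi_score": 0.5},
            "desmoplastic stroma": {"vi_score": 0.8},
            "VI focus": {"vi_score": 1.5},
        })
    noise_sd: float = 0.2
    detected_genes_mean: float = 1000.0
    low_depth_fraction: float = 0.0
    gene_rates: dict[str, float] | None = None  # enables Poisson count mode
    seed: int = 0

    def validate(self) -> None:
        if self.spot_spacing_um <= 0:
            raise ValueError("spot_spacing_um must be positive")
        if not self.region_layout and not self.background_label:
            raise ValueError("empty region layout")


def generate_spot_sample(config: SpotConfig) -> SpotSample:
    """Simulate one annotated spot lattice with region-specific score means.

    Scores are region mean + N(0, noise_sd) per spot. When ``gene_rates``
    is set, a spot x gene Poisson count table is attached for pseudo-bulk
    tests. A ``low_depth_fraction`` of spots is planted below a detected-
    gene count of 250 to exercise spot QC.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rr, cc = np.meshgrid(np.arange(config.grid_rows), np.arange(config.grid_cols),
                         indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    n = rr.size
    ann = np.full(n, config.background_label, dtype=object)
    for label, blocks in config.region_layout.items():
        for (r0, r1, c0, c1) in blocks:
            ann[(rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)] = label

    spots = pd.DataFrame({
        "spot_id": [f"spot_{i:04d}" for i in range(n)],
        "x_um": cc * config.spot_spacing_um,
        "y_um": rr * config.spot_spacing_um,
        "annotation": ann,
    })
    detected = np.maximum(
        rng.normal(config.detected_genes_mean, config.detected_genes_mean / 10, n), 1
    ).astype(int)
    if config.low_depth_fraction > 0:
        n_low = int(round(config.low_depth_fraction * n))
        low = rng.choice(n, size=n_low, replace=False)
        detected[low] = rng.integers(10, 250, size=n_low)
    spots["n_genes_detected"] = detected

    score_names = sorted({s for means in config.region_score_means.values() for s in means})
    for name in score_names:
        mean = np.array([config.region_score_means.get(a, {}).get(name, 0.0) for a in ann])
        spots[name] = mean + rng.normal(0.0, config.noise_sd, size=n)

    counts = None
    if config.gene_rates is not None:
        genes = list(config.gene_rates)
        rates = np.array([config.gene_rates[g] for g in genes], dtype=float)
        counts = pd.DataFrame(rng.poisson(rates[None, :].repeat(n, axis=0)),
                              columns=genes)
    return SpotSample(spots, config.spot_spacing_um, config.spot_diameter_um, counts)


def generate_biopsy_pairs(n_pairs: int = 24, target_correlation: float = 0.77,
                          vi_fraction: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Simulate paired biopsy/resection predictor scores.

    Latent scores are bivariate normal with the requested correlation
    (biopsy sampling attenuates the resection score); VI labels are
    thresholded so that exactly round(vi_fraction * n) pairs are positive.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    if not -1.0 <= target_correlation <= 1.0:
        raise ValueError("|target_correlation| must be <= 1")
    if not 0.0 < vi_fraction < 1.0:
        raise ValueError("vi_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    z1, z2 = rng.normal(size=(2, n_pairs))
    resection = z1
    biopsy = target_correlation * z1 + np.sqrt(1.0 - target_correlation**2) * z2
    n_pos = int(round(vi_fraction * n_pairs))
    order = np.argsort(-resection, kind="stable")
    vi = np.zeros(n_pairs, dtype=int)
    vi[order[:n_pos]] = 1
    if vi.sum() in (0, n_pairs):
        warnings.warn("degenerate label split")
    return pd.DataFrame({
        "pair_id": [f"p{i:02d}" for i in range(n_pairs)],
        "biopsy_score": biopsy,
        "resection_score": resection,
        "vi": vi,
    })
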