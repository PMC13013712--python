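"""Shared fixtures: the default synthetic discovery cohort and derived objects.

Session-scoped so that the expensive pipeline stages (DE, clustering,
final model) are computed once and reused across test modules.
"""

import numpy as np
import pytest

import visig


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default discovery cohort: n=100, 30% VI, 474 planted signature genes."""
    return visig.generate_bulk_cohort(visig.CohortConfig())


@pytest.fixture(scope="session")
def filtered_cm(bulk_cohort):
    cm, _, _ = bulk_cohort
    return visig.with_tmm(visig.filter_genes(cm))


@pytest.fixture(scope="session")
def de_result(filtered_cm, bulk_cohort):
    _, meta, _ = bulk_cohort
    return visig.nb_glm_lrt(filtered_cm, visig.grade_design(meta), contrast="VI")


@pytest.fixture(scope="session")
def signature_z(filtered_cm, de_result):
    """(genes, z-matrix) of the FDR<0.01 significant set."""
    genes = de_result.significant(0.01)["gene_id"].tolist()
    z = visig.zscore_by_gene(visig.log_cpm(filtered_cm).subset_genes(genes))
    return genes, z


@pytest.fixture(scope="session")
def truth_cluster_of(bulk_cohort):
    _, _, truth = bulk_cohort
    return {g: c for c, gs in truth.cluster_genes.items() for g in gs}


@pytest.fixture(scope="session")
def null_de():
    """DE on a cohort generated with all planted effects zero."""
    cfg = visig.CohortConfig(cluster_log2fc=(0.0, 0.0, 0.0, 0.0), seed=0)
    cm, meta, _ = visig.generate_bulk_cohort(cfg)
    cmf = visig.with_tmm(visig.filter_genes(cm))
    return visig.nb_glm_lrt(cmf, visig.grade_design(meta), contrast="VI")


@pytest.fixture(scope="session")
def final_model(bulk_cohort):
    cm, meta, _ = bulk_cohort
    return visig.train_final(cm, meta, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def make_de_clusters():
    """Factory for a synthetic DE table + cluster partition of given sizes."""
    from visig.signature import DEResult, GeneClusterSignature
    import pandas as pd

    def build(sizes=(115, 37, 182, 140)):
        r = np.random.default_rng(0)
        genes, labels = [], []
        for c, size in enumerate(sizes, start=1):
            genes.extend(f"c{c}_{i:03d}" for i in range(size))
            labels.extend([c] * size)
        n = len(genes)
        tab = pd.DataFrame({
            "gene_id": genes,
            "log2fc": np.where(np.array(labels) == 4, -1.0, 1.0),
            "lrt": 10.0, "df": 1,
            "pvalue": r.uniform(1e-8, 1e-4, n),
            "qvalue": 1e-4, "mean_logcpm": 5.0,
        })
        de = DEResult(tab)
        clusters = GeneClusterSignature(
            genes, np.array(labels), 4, {1: "up", 2: "up", 3: "up", 4: "down"})
        return de, clusters

    return build
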