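import numpy as np
import pandas as pd
import pytest

import canprio as cp
from canprio.synthetic import region_set_for


@pytest.fixture(scope="session")
def candidate_table():
    """Packaged 32-gene feedforward-CAN candidate phenotype table."""
    return cp.load_candidate_table()


@pytest.fixture(scope="session")
def blockdiag_bundle():
    """Block-diagonal synthetic matrix: 7 region classes, every gene a
    single-class marker (one gene cluster), strong signal-to-noise."""
    cfg = cp.SyntheticConfig(
        n_genes=70,
        n_regions=47,
        k_region_clusters=7,
        k_gene_clusters=1,
        n_informative_genes=70,
        signal=5.0,
        noise_sd=1.0,
        seed=11,
    )
    matrix, truth = cp.generate_expression(cfg)
    return cfg, matrix, truth, region_set_for(cfg, truth)


@pytest.fixture()
def two_gene_cluster_matrix():
    """Zero-noise matrix with 2 planted gene clusters and no informative bumps."""
    cfg = cp.SyntheticConfig(
        n_genes=40,
        n_regions=47,
        k_region_clusters=7,
        k_gene_clusters=2,
        n_informative_genes=0,
        signal=3.0,
        noise_sd=0.0,
        seed=1,
    )
    matrix, truth = cp.generate_expression(cfg)
    return cfg, matrix, truth, region_set_for(cfg, truth)


def write_expression_tsv(path, frame: pd.DataFrame) -> None:
    out = frame.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


@pytest.fixture()
def small_matrix_file(tmp_path):
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["rA", "rB"]
    )
    p = tmp_path / "m.tsv"
    write_expression_tsv(p, frame)
    return p
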