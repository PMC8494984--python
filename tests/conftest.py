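from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from triopattern.io import CrossSpec, ExpressionDataset, SampleMeta

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


def make_random_trios(n: int, rng: np.random.Generator, threshold: float = 1.0) -> pd.DataFrame:
    """Random valid trios: each member off with prob 1/4, else log-normal FPKM.

    All-silent trios are dropped, so every row satisfies the classifier's
    precondition.  Expressed flags are derived from the threshold, mirroring
    how build_trios produces them.
    """
    values = np.exp(rng.normal(2.0, 1.5, size=(n, 3)))
    off = rng.random((n, 3)) < 0.25
    values[off] = 0.0
    keep = ~(values < threshold).all(axis=1)
    values = values[keep]
    m = len(values)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(m)],
            "hybrid": "H1",
            "tissue": "L",
            "p1_value": values[:, 0],
            "p2_value": values[:, 1],
            "f1_value": values[:, 2],
            "p1_expressed": values[:, 0] >= threshold,
            "p2_expressed": values[:, 1] >= threshold,
            "f1_expressed": values[:, 2] >= threshold,
        }
    )


def make_two_parent_dataset(values_a, values_b, parent_a="Z", parent_b="C", tissue="L"):
    """Minimal in-memory dataset with one replicate per parent, no crosses."""
    genes = [f"g{i}" for i in range(len(values_a))]
    matrix = pd.DataFrame(
        {f"{parent_a}_{tissue}1": values_a, f"{parent_b}_{tissue}1": values_b},
        index=pd.Index(genes, name="gene_id"),
        dtype=float,
    )
    samples = [
        SampleMeta(f"{parent_a}_{tissue}1", parent_a, tissue, 1),
        SampleMeta(f"{parent_b}_{tissue}1", parent_b, tissue, 1),
    ]
    return ExpressionDataset(matrix=matrix, samples=samples, design=[])


@pytest.fixture
def tiny_dataset_files(tmp_path):
    """3-gene x 6-sample TSV trio on disk: one cross (H = A x B), one tissue."""
    matrix = "\n".join(
        [
            "gene_id\tA_L1\tA_L2\tB_L1\tB_L2\tH_L1\tH_L2",
            "g1\t10.0\t12.0\t2.0\t2.4\t6.0\t6.6",
            "g2\t5.0\t5.5\t0.0\t0.0\t0.0\t0.1",
            "g3\t0.0\t0.2\t0.3\t0.1\t0.0\t0.0",
        ]
    )
    samples = "\n".join(
        [
            "sample_id\tgenotype\ttissue\treplicate",
            "A_L1\tA\tL\t1",
            "A_L2\tA\tL\t2",
            "B_L1\tB\tL\t1",
            "B_L2\tB\tL\t2",
            "H_L1\tH\tL\t1",
            "H_L2\tH\tL\t2",
        ]
    )
    design = "hybrid\tparent1\tparent2\nH\tA\tB"
    paths = {
        "matrix_path": tmp_path / "matrix.tsv",
        "samples_path": tmp_path / "samples.tsv",
        "design_path": tmp_path / "design.tsv",
    }
    paths["matrix_path"].write_text(matrix + "\n")
    paths["samples_path"].write_text(samples + "\n")
    paths["design_path"].write_text(design + "\n")
    return paths
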