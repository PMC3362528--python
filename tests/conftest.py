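"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest

from naksense import ExpressionMatrix, SampleDesign, Scale


def make_matrix(values, gene_ids=None, sample_ids=None, scale=Scale.LOG2):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale
    )


def make_design(cells=("hela",), calciums=("plus",),
                treatments=("control", "ouabain"), n_reps=4):
    rows = []
    for cell in cells:
        for ca in calciums:
            for tr in treatments:
                for rep in range(1, n_reps + 1):
                    rows.append((f"{cell}_{ca}_{tr}_{rep}", cell, tr, ca, rep))
    return SampleDesign(pd.DataFrame(
        rows,
        columns=["sample_id", "cell_type", "treatment", "calcium", "replicate"],
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
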