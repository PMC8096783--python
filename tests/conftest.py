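import numpy as np
import pandas as pd
import pytest

from decif import (ExpressionMatrix, GenePanel, SignatureStatus,
                   default_ecm_panel, default_ifn_panel, simulate_expression)


@pytest.fixture(scope="session")
def panels():
    return default_ecm_panel(), default_ifn_panel()


@pytest.fixture(scope="session")
def cohort(panels):
    """A mid-size planted cohort shared by recovery tests (read-only)."""
    ecm, ifn = panels
    expr, truth = simulate_expression(n_samples=150, ecm_panel=ecm, ifn_panel=ifn,
                                      delta=2.0, n_noise_genes=100, seed=42)
    return expr, truth


@pytest.fixture
def tiny_expr():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [0.0, 1.0, 0.0, 1.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"])
    return ExpressionMatrix(data, "toy")


def make_status(name, sample_ids, positives, scores=None):
    status = pd.Series([s in set(positives) for s in sample_ids], index=sample_ids)
    score = pd.Series(scores if scores is not None else 0.0, index=sample_ids,
                      dtype=float)
    return SignatureStatus(name, status, score)
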