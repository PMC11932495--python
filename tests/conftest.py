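import numpy as np
import pandas as pd
import pytest

from comarker.expression import CASE, CONTROL, ExpressionStudy
from comarker.pipeline import run_synthetic_pipeline
from comarker.synth import SyntheticDesign


def make_study(case_values, control_values, scale="log2", disease_id="demo"):
    """Study from per-gene lists of case and control values (genes x samples)."""
    case = np.atleast_2d(np.asarray(case_values, dtype=float))
    ctrl = np.atleast_2d(np.asarray(control_values, dtype=float))
    x = np.hstack([case, ctrl])
    genes = [f"g{i}" for i in range(x.shape[0])]
    samples = [f"case{i}" for i in range(case.shape[1])] + [
        f"ctrl{i}" for i in range(ctrl.shape[1])
    ]
    groups = pd.Series([CASE] * case.shape[1] + [CONTROL] * ctrl.shape[1], index=samples)
    return ExpressionStudy(
        disease_id=disease_id,
        values=pd.DataFrame(x, index=genes, columns=samples),
        sample_groups=groups,
        scale=scale,
    )


@pytest.fixture(scope="session")
def default_pipeline_result():
    """Full pipeline on the default synthetic design (shared across tests)."""
    return run_synthetic_pipeline(SyntheticDesign(seed=20240917 % 2**31))


@pytest.fixture
def small_design():
    return SyntheticDesign(
        n_genes=300,
        n_diseases=3,
        cases_per_disease=20,
        controls_per_disease=20,
        n_shared_up=30,
        n_shared_down=40,
        n_private_deg=10,
        module_spec=((40, 0.8),),
        seed=11,
    )
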