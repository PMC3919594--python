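import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rewirenet.synthgen import ExpressionStudy

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def build_study(baseline: np.ndarray, stress: np.ndarray,
                gene_ids=None, base_inds=None, stress_inds=None) -> ExpressionStudy:
    """Assemble an ExpressionStudy from two genes × individuals arrays."""
    baseline = np.asarray(baseline, dtype=float)
    stress = np.asarray(stress, dtype=float)
    genes = gene_ids or [f"g{i:04d}" for i in range(baseline.shape[0])]
    base_inds = base_inds or [f"ind{i:03d}" for i in range(baseline.shape[1])]
    stress_inds = stress_inds or [f"ind{i:03d}" for i in range(stress.shape[1])]
    mats = {
        "baseline": pd.DataFrame(baseline, index=genes,
                                 columns=[f"baseline_{i}" for i in base_inds]),
        "stress": pd.DataFrame(stress, index=genes,
                               columns=[f"stress_{i}" for i in stress_inds]),
    }
    rows = [(f"baseline_{i}", i, "baseline") for i in base_inds]
    rows += [(f"stress_{i}", i, "stress") for i in stress_inds]
    samples = pd.DataFrame(rows, columns=["sample_id", "individual_id",
                                          "condition"]).set_index("sample_id")
    return ExpressionStudy(matrices=mats, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
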