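import numpy as np
import pandas as pd
import pytest

from embryoarray.containers import ExpressionMatrix


def make_sample_sheet(genotypes=("WT", "vtc2"), stages=("s",), reps=2):
    rows = []
    for g in genotypes:
        for s in stages:
            for r in range(1, reps + 1):
                rows.append({"sample_id": f"{g}_{s}_r{r}", "genotype": g,
                             "stage": s, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def make_matrix(values, samples=None) -> ExpressionMatrix:
    if samples is None:
        samples = make_sample_sheet()
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=[f"g{i}" for i in range(len(values))],
            columns=list(samples.index),
        )
    return ExpressionMatrix(values, samples)


@pytest.fixture
def two_group_samples():
    """Single-stage 2-vs-2 design: WT_s_r1, WT_s_r2, vtc2_s_r1, vtc2_s_r2."""
    return make_sample_sheet()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
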