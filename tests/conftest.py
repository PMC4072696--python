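import numpy as np
import pandas as pd
import pytest

from mirloop.types import ExpressionMatrix, SampleDesign


def make_matrix(values, feature_ids=None, sample_ids=None, kind="mRNA"):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                         columns=sample_ids)
    return ExpressionMatrix(frame, kind)


def make_design(n_normal, n_tumor, sample_ids=None, pair_ids=None):
    n = n_normal + n_tumor
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return SampleDesign(pd.DataFrame({
        "sample_id": sample_ids,
        "condition": ["normal"] * n_normal + ["tumor"] * n_tumor,
        "subtype": ["unknown"] * n,
        "pair_id": pair_ids or [""] * n,
    }))


def make_de_frame(t_values, feature_ids=None, p=None, fdr=None):
    """Build a differential-expression result frame from raw statistics."""
    t = np.asarray(t_values, dtype=float)
    feature_ids = feature_ids or [f"g{i}" for i in range(t.size)]
    return pd.DataFrame(
        {
            "delta": t,
            "t_mod": t,
            "p": np.ones_like(t) if p is None else np.asarray(p, dtype=float),
            "fdr": np.ones_like(t) if fdr is None else np.asarray(fdr, dtype=float),
            "direction": np.where(t >= 0, 1, -1),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


@pytest.fixture
def small_two_group():
    """12 samples, 60 features, strong planted shift in the first 6 features."""
    rng = np.random.default_rng(42)
    vals = rng.normal(5.0, 0.3, size=(60, 12))
    vals[:6, 6:] += 2.0
    return make_matrix(vals), make_design(6, 6)
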