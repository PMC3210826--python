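import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from toxsetpipe.containers import DesignTable, ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # factories below are stateless, so sharing them across examples is safe
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture
def make_design():
    """Factory for a balanced two-group design table."""

    def _make(n_per_group: int = 4) -> DesignTable:
        samples = [f"c{i + 1}" for i in range(n_per_group)] + [
            f"t{i + 1}" for i in range(n_per_group)
        ]
        return DesignTable(
            pd.DataFrame(
                {
                    "sample": samples,
                    "group": ["control"] * n_per_group + ["treated"] * n_per_group,
                }
            )
        )

    return _make


@pytest.fixture
def make_matrix():
    """Factory wrapping a 2-D array into an ExpressionMatrix."""

    def _make(values, samples=None, probes=None, log_scale=True, annotations=None):
        values = np.asarray(values, dtype=float)
        if samples is None:
            n_cols = values.shape[1]
            if n_cols % 2 == 0:
                # default naming matches the two-group design factory
                half = n_cols // 2
                samples = [f"c{j + 1}" for j in range(half)] + [
                    f"t{j + 1}" for j in range(half)
                ]
            else:
                samples = [f"s{j + 1}" for j in range(n_cols)]
        probes = probes or [f"g{i + 1:04d}" for i in range(values.shape[0])]
        return ExpressionMatrix(
            pd.DataFrame(values, index=probes, columns=samples),
            annotations=annotations,
            log_scale=log_scale,
        )

    return _make
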