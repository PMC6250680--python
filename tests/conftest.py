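import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phosplice.phospho import META_COLUMNS, ReporterMatrix

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_reporter_matrix(intensities, case_channels=1, **meta_overrides) -> ReporterMatrix:
    """Reporter matrix from a raw intensity array, one fragment row per entry.

    The first ``case_channels`` columns are case channels, the rest control.
    Metadata defaults to rows that pass every filter; override per-column with
    a list via ``meta_overrides``.
    """
    inten = np.atleast_2d(np.asarray(intensities, dtype=float))
    n_rows, n_ch = inten.shape
    channels = [f"case{i + 1}" for i in range(case_channels)] + [
        f"control{i + 1}" for i in range(n_ch - case_channels)
    ]
    meta = {
        "peptide": [f"pep{i}" for i in range(n_rows)],
        "fragment": [0] * n_rows,
        "protein": ["PROT1"] * n_rows,
        "site": ["S1"] * n_rows,
        "confidence": [0.99] * n_rows,
        "has_itraq_label": [True] * n_rows,
        "shared_spectrum": [False] * n_rows,
    }
    meta.update(meta_overrides)
    data = pd.DataFrame(meta)[META_COLUMNS]
    for j, c in enumerate(channels):
        data[c] = inten[:, j]
    groups = {c: ("case" if c.startswith("case") else "control") for c in channels}
    return ReporterMatrix(data=data, channels=channels, groups=groups)


@pytest.fixture
def reporter_matrix_factory():
    return make_reporter_matrix
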