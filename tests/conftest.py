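import numpy as np
import pandas as pd
import pytest

from lcsmix.data import PanelDataset
from lcsmix.recovery import run_recovery


def make_panel(y, observed=None, covariates=None, outcomes=None, score_range=None):
    """Small PanelDataset builder for hand-constructed fixtures."""
    y = np.asarray(y, dtype=float)
    if observed is None:
        observed = ~np.isnan(y)
    n = y.shape[0]
    return PanelDataset(
        subject_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        y=np.where(observed, y, np.nan),
        observed=np.asarray(observed, dtype=bool),
        covariates=covariates if covariates is not None else pd.DataFrame(index=range(n)),
        outcomes=outcomes if outcomes is not None else pd.DataFrame(index=range(n)),
        score_range=score_range,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """One full default recovery experiment (n=4361, 50-start EM, 3-step),
    shared by the acceptance tests and the slower recovery checks."""
    return run_recovery(seed=0)
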