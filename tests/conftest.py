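import numpy as np
import pandas as pd
import pytest

from fedrad import GeneratorConfig, SiteDataset, generate_federation


def make_site(values, outcome=None, site_id="s", columns=None, **kwargs):
    """Build a SiteDataset from a plain array (NaN = missing)."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1 and arr.shape[1] > 1 and outcome is not None and len(outcome) > 1:
        arr = arr.T
    cols = columns or [f"f{j}" for j in range(arr.shape[1])]
    if outcome is None:
        outcome = np.zeros(arr.shape[0])
    return SiteDataset(
        site_id=site_id,
        features=pd.DataFrame(arr, columns=cols),
        outcome=pd.Series(np.asarray(outcome, dtype=float)),
        **kwargs,
    )


@pytest.fixture(scope="session")
def federation4():
    """Well-conditioned 4-site federation with three informative clusters."""
    cfg = GeneratorConfig(
        num_sites=4,
        patients_per_site=[206, 441, 100, 141],
        num_clusters=4,
        features_per_cluster=4,
        within_cluster_corr=0.7,
        between_cluster_corr=0.05,
        true_coefficients={"c01_f01": 1.0, "c02_f01": -0.8, "c03_f01": 0.6},
        seed=11,
    )
    return generate_federation(cfg)
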