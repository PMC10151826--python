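import numpy as np
import pandas as pd
import pytest

from genosleep import synthetic_data as synth


@pytest.fixture
def small_panel():
    """Five valid instruments with fixed specs."""
    return synth.random_snp_panel(5, seed=11)


@pytest.fixture
def toy_harmonized():
    """Three-instrument harmonized summary-stat table with exact values."""
    return pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "A", "A"],
            "other_allele": ["G", "G", "G"],
            "eaf_exposure": [0.2, 0.3, 0.4],
            "beta_exposure": [0.5, 0.4, 0.25],
            "se_exposure": [0.05, 0.04, 0.05],
            "eaf_outcome": [0.2, 0.3, 0.4],
            "beta_outcome": [0.15, 0.10, 0.08],
            "se_outcome": [0.03, 0.02, 0.02],
            "harmonized": True,
        }
    )


@pytest.fixture
def survival_toy():
    """Six subjects, one censoring, hand-checkable product-limit values."""
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "time": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 1, 1, 0, 1, 1],
            "group": "a",
        }
    )


def marginal_ols_oracle(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Independent simple-regression oracle: explicit normal equations."""
    n = len(y)
    xm = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
    resid = y - xm @ beta
    sigma2 = resid @ resid / (n - 2)
    cov = sigma2 * np.linalg.inv(xm.T @ xm)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))
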