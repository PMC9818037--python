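import numpy as np
import pytest

from copulasurv.simulate import COVARIATE_ORDER, default_config, generate_cohort


@pytest.fixture(scope="session")
def covariates():
    return list(COVARIATE_ORDER)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort at the study's default conditions, n = 600."""
    cfg = default_config(n=600, seed=42)
    df, manifest = generate_cohort(cfg)
    return df, manifest, cfg


@pytest.fixture(scope="session")
def fitted_small(small_cohort, covariates):
    """A fitted log-logistic-Clayton model shared across diagnostic tests."""
    from copulasurv import CopulaSurvivalModel

    df, _, cfg = small_cohort
    model = CopulaSurvivalModel.from_dataframe(df, covariates=covariates)
    return model.fit()


def mc_tau_se(pairs: np.ndarray, n_batches: int = 40):
    """Monte-Carlo mean and standard error of Kendall's tau via batch means."""
    from scipy.stats import kendalltau

    n = pairs.shape[0] // n_batches
    taus = [kendalltau(pairs[i * n:(i + 1) * n, 0],
                       pairs[i * n:(i + 1) * n, 1]).statistic
            for i in range(n_batches)]
    taus = np.asarray(taus)
    return float(np.mean(taus)), float(np.std(taus, ddof=1) / np.sqrt(n_batches))
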