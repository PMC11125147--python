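import numpy as np
import pytest

from begp import (
    DayRecord,
    SimConfig,
    build_basis,
    estimate_baseline,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def basis13():
    """The default diurnal system: 13 cubic B-splines on [0, 24] h."""
    return build_basis(13, 4)


@pytest.fixture(scope="session")
def basis5():
    return build_basis(5, 4)


@pytest.fixture(scope="session")
def const_basis():
    """P=1, order=1: the single constant basis function."""
    return build_basis(1, 1)


def make_model_days(
    basis,
    n_days,
    n_obs,
    coef_mean,
    coef_cov,
    noise_sd,
    rng,
):
    """Days drawn exactly from the additive model: C_i ~ N(mean, cov),
    y = Phi^T C_i + N(0, noise_sd^2), uniform random timestamps."""
    from begp import evaluate_basis

    p = basis.n_basis
    chol = np.linalg.cholesky(coef_cov + 1e-12 * np.eye(p))
    days = []
    for i in range(n_days):
        t = np.sort(
            rng.uniform(basis.domain.t_start, basis.domain.t_end, size=n_obs)
        )
        c_i = coef_mean + chol @ rng.standard_normal(p)
        phi = evaluate_basis(basis, t).matrix
        y = phi.T @ c_i + noise_sd * rng.standard_normal(n_obs)
        days.append(DayRecord(day_index=i + 1, timestamps=t, values=y))
    return days


@pytest.fixture(scope="session")
def default_sim(basis13):
    """One synthetic subject at the default study-like conditions."""
    return simulate_dataset(SimConfig(seed=7), basis13)


@pytest.fixture(scope="session")
def fitted_baseline(basis13, default_sim):
    return estimate_baseline(default_sim.days, basis13)
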