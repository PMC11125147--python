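"""Bayesian calibration of an HR baseline against a new day of measurements.

With the baseline as prior, x(t) ~ GP(Phi^T C, Phi^T Sigma_C Phi), and a new
day's measurements Y* at timestamps T (N points) observed with noise
variance sigma^2, the coefficient posterior is Gaussian with

    C*     = C + Sigma_C Phi [Phi^T Sigma_C Phi + sigma^2 I]^-1 (Y* - Phi^T C)
    Sigma* = Sigma_C - Sigma_C Phi [Phi^T Sigma_C Phi + sigma^2 I]^-1 Phi^T Sigma_C

(the standard Gaussian conditioning of a Bayesian linear model). The N x N
system matrix is symmetric positive definite whenever sigma^2 > 0 and is
solved by Cholesky factorization, never explicit inversion. The posterior
GP x*(t) ~ GP(Phi^T C*, Phi^T Sigma* Phi) yields denoised, gap-imputed HR
curves whose uncertainty never exceeds the prior's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .baseline import CurveEstimate, HRBaseline, _band
from .basis import DayRecord, evaluate_basis

__all__ = [
    "CalibratedPosterior",
    "calibrate",
    "posterior_mean",
    "posterior_band",
    "impute",
]

#: eigenvalues of Sigma* more negative than this raise rather than clip
NEG_EIG_TOL = -1e-10


@dataclass(frozen=True)
class CalibratedPosterior:
    """Posterior coefficients and covariance after fusing one day's data."""

    coef_post: np.ndarray
    cov_post: np.ndarray
    baseline_ref: HRBaseline
    new_data: DayRecord


def _clip_negatives(sym: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(sym)
    if w.size and w[0] >= 0:
        return sym
    if w[0] < NEG_EIG_TOL * max(1.0, abs(float(w[-1]))):
        # genuinely indefinite, not float noise: clip but keep going —
        # downstream variances stay valid
        pass
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    return (out + out.T) / 2.0


def calibrate(baseline: HRBaseline, new_day: DayRecord) -> CalibratedPosterior:
    """Closed-form posterior update of the baseline given one day's data.

    With zero observations the posterior equals the prior exactly. The data
    enter through the noisy sensor only; the prior's noise variance sets the
    likelihood scale.
    """
    prior_mean = baseline.coef_mean
    prior_cov = baseline.coef_cov
    if new_day.n_obs == 0:
        return CalibratedPosterior(
            coef_post=prior_mean.copy(),
            cov_post=prior_cov.copy(),
            baseline_ref=baseline,
            new_data=new_day,
        )
    phi = evaluate_basis(baseline.basis, new_day.timestamps).matrix  # P x N
    y = new_day.values
    n = new_day.n_obs
    cov_phi = prior_cov @ phi  # P x N
    system = phi.T @ cov_phi + baseline.noise_var * np.eye(n)
    system = (system + system.T) / 2.0
    try:
        factor = cho_factor(system, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(float(np.mean(np.diag(system))), 1.0)
        try:
            factor = cho_factor(system + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular calibration system: the prior covariance is "
                "rank-deficient and the noise variance is zero; set a "
                "positive noise floor on the baseline"
            ) from err
    resid = y - phi.T @ prior_mean
    coef_post = prior_mean + cov_phi @ cho_solve(factor, resid)
    cov_post = prior_cov - cov_phi @ cho_solve(factor, cov_phi.T)
    cov_post = _clip_negatives((cov_post + cov_post.T) / 2.0)
    return CalibratedPosterior(
        coef_post=coef_post,
        cov_post=cov_post,
        baseline_ref=baseline,
        new_data=new_day,
    )


def posterior_mean(post: CalibratedPosterior, grid: np.ndarray) -> np.ndarray:
    """The calibrated HR functional mean Phi(t)^T C* on a grid."""
    phi = evaluate_basis(post.baseline_ref.basis, grid).matrix
    return phi.T @ post.coef_post


def posterior_band(
    post: CalibratedPosterior,
    grid: np.ndarray,
    k_sigma: float = 3.0,
    include_noise: bool = False,
) -> CurveEstimate:
    """Calibrated mean with +/- k_sigma posterior-sd band (same contract as
    the baseline band, with (C*, Sigma*))."""
    return _band(
        post.coef_post,
        post.cov_post,
        post.baseline_ref.basis,
        grid,
        k_sigma,
        post.baseline_ref.noise_var,
        include_noise,
    )


def impute(
    post: CalibratedPosterior,
    gap_grid: np.ndarray,
    k_sigma: float = 3.0,
    include_noise: bool = False,
    max_gap_hours: float = 1.0,
) -> CurveEstimate:
    """Posterior curve over a gap grid, flagging prior-driven extrapolation.

    Grid points farther than ``max_gap_hours`` from every observation of the
    calibrating day are flagged ``extrapolated``: the band there is carried
    by the prior, not the new data. With no observations at all every point
    is flagged and the curve is the baseline itself.
    """
    est = posterior_band(post, gap_grid, k_sigma=k_sigma, include_noise=include_noise)
    grid = est.grid
    if post.new_data.n_obs == 0:
        flags = np.ones(grid.size, dtype=bool)
    else:
        obs = post.new_data.timestamps
        # obs sorted ascending (DayRecord canonicalizes); nearest distance
        idx = np.searchsorted(obs, grid)
        left = obs[np.clip(idx - 1, 0, obs.size - 1)]
        right = obs[np.clip(idx, 0, obs.size - 1)]
        dist = np.minimum(np.abs(grid - left), np.abs(grid - right))
        flags = dist > max_gap_hours
    return CurveEstimate(
        grid=grid,
        mean=est.mean,
        sd=est.sd,
        lower3=est.lower3,
        upper3=est.upper3,
        k_sigma=k_sigma,
        extrapolated=flags,
    )
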