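"""Personalized heart-rate baseline: the Gaussian-process prior.

Pooling M per-day coefficient fits gives a method-of-moments prior for a
subject's diurnal pattern:

    C-bar    = (1/M) sum_i C-hat_i                       (coefficient mean)
    S_C      = (1/(M-1)) sum_i (C-hat_i - C-bar)(...)^T  (sample covariance)
    Sigma_C  = S_C - (sigma^2 / M) sum_i (Phi_i Phi_i^T)^-1   (debiased)

The debiasing subtracts the average estimation noise of the per-day least
squares, so E[Sigma_C-hat] equals the true between-day coefficient
covariance. In finite samples the debiased matrix can be indefinite; it is
repaired by eigenvalue clipping before it enters any variance computation.

The baseline defines a Gaussian process x(t) ~ GP(mu, k) with

    mu(t)    = Phi(t)^T C-bar,
    k(t,tau) = Phi(t)^T Sigma_C Phi(tau),

whose mean +/- 3 sd band quantifies the subject's plausible HR range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import (
    BasisSystem,
    DayRecord,
    DayFit,
    InvalidConfigurationError,
    ModelConfig,
    TimeDomain,
    build_basis,
    estimate_noise_variance,
    evaluate_basis,
    fit_day,
)

__all__ = [
    "HRBaseline",
    "CurveEstimate",
    "estimate_baseline",
    "psd_repair",
    "baseline_mean",
    "baseline_cov",
    "baseline_band",
    "save_baseline",
    "load_baseline",
]


class InsufficientDataError(ValueError):
    """Fewer than two usable days survive filtering."""


@dataclass(frozen=True)
class CurveEstimate:
    """A curve with pointwise uncertainty on a time grid.

    ``lower3``/``upper3`` are mean -/+ k_sigma * sd; ``extrapolated`` marks
    grid points far from any observation (only set by gap imputation).
    """

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lower3: np.ndarray
    upper3: np.ndarray
    k_sigma: float = 3.0
    extrapolated: np.ndarray | None = None


@dataclass(frozen=True)
class HRBaseline:
    """The estimated prior for one subject's diurnal heart-rate pattern."""

    coef_mean: np.ndarray
    coef_cov: np.ndarray
    coef_cov_raw: np.ndarray
    sample_cov: np.ndarray
    noise_var: float
    n_days: int
    basis: BasisSystem
    excluded_days: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_basis(self) -> int:
        return int(self.coef_mean.size)


def psd_repair(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    The input is symmetrized first; negative eigenvalues are clipped to
    zero. Idempotent on PSD inputs. This is the nearest PSD matrix in
    Frobenius norm among symmetric matrices.
    """
    a = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("psd_repair requires finite entries")
    sym = (a + a.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.size and w[0] >= 0:
        return sym
    w_clipped = np.clip(w, 0.0, None)
    out = (v * w_clipped) @ v.T
    return (out + out.T) / 2.0


def estimate_baseline(
    days: list[DayRecord],
    basis: BasisSystem,
    config: ModelConfig | None = None,
) -> HRBaseline:
    """Estimate a subject's HR baseline from multi-day records.

    Days with fewer than ``config.min_obs`` observations, or whose design is
    numerically rank-deficient at ridge 0, are excluded (and listed with the
    reason). At least two usable days are required; M in the estimators is
    the number of retained days.
    """
    config = config or ModelConfig(
        n_basis=basis.n_basis, spline_order=basis.order
    )
    fits: list[DayFit] = []
    excluded: list[tuple[int, str]] = []
    for day in days:
        if day.n_obs < config.min_obs:
            excluded.append(
                (day.day_index, f"only {day.n_obs} obs (< {config.min_obs})")
            )
            continue
        fit = fit_day(basis, day, ridge=config.ridge)
        if not fit.rank_ok and config.ridge == 0:
            excluded.append((day.day_index, "rank-deficient design"))
            continue
        if fit.gram_cond > config.max_day_gram_cond:
            excluded.append(
                (
                    day.day_index,
                    f"ill-conditioned design (cond {fit.gram_cond:.1e}); "
                    "a gap likely covers a basis function's support",
                )
            )
            continue
        fits.append(fit)
    m = len(fits)
    if m < 2:
        raise InsufficientDataError(
            f"only {m} usable day(s) after filtering; need at least 2 "
            f"(excluded: {excluded})"
        )

    coefs = np.stack([f.coefficients for f in fits])  # M x P
    coef_mean = coefs.mean(axis=0)
    dev = coefs - coef_mean
    sample_cov = dev.T @ dev / (m - 1)
    noise_var = estimate_noise_variance(fits)
    gram_inv_mean = sum(f.gram_inverse for f in fits) / m
    coef_cov_raw = sample_cov - noise_var * gram_inv_mean
    coef_cov = psd_repair(coef_cov_raw)
    return HRBaseline(
        coef_mean=coef_mean,
        coef_cov=coef_cov,
        coef_cov_raw=coef_cov_raw,
        sample_cov=sample_cov,
        noise_var=noise_var,
        n_days=m,
        basis=basis,
        excluded_days=excluded,
    )


def baseline_mean(baseline: HRBaseline, grid: np.ndarray) -> np.ndarray:
    """Evaluate the functional mean mu(t) = Phi(t)^T C-bar on a grid."""
    phi = evaluate_basis(baseline.basis, grid).matrix
    return phi.T @ baseline.coef_mean


def baseline_cov(baseline: HRBaseline, t: float, tau: float) -> float:
    """Evaluate the covariance function k(t, tau) = Phi(t)^T Sigma_C Phi(tau)."""
    phi_t = evaluate_basis(baseline.basis, np.atleast_1d(t)).matrix[:, 0]
    phi_tau = evaluate_basis(baseline.basis, np.atleast_1d(tau)).matrix[:, 0]
    # evaluate both orders and average: exact symmetry under float rounding
    fwd = float(phi_t @ baseline.coef_cov @ phi_tau)
    bwd = float(phi_tau @ baseline.coef_cov @ phi_t)
    return 0.5 * (fwd + bwd)


def _band(
    coef_mean: np.ndarray,
    coef_cov: np.ndarray,
    basis: BasisSystem,
    grid: np.ndarray,
    k_sigma: float,
    noise_var: float,
    include_noise: bool,
) -> CurveEstimate:
    if k_sigma < 0:
        raise InvalidConfigurationError("k_sigma must be >= 0")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    phi = evaluate_basis(basis, grid).matrix  # P x G
    mean = phi.T @ coef_mean
    var = np.einsum("pg,pq,qg->g", phi, coef_cov, phi)
    var = np.clip(var, 0.0, None)
    if include_noise:
        var = var + noise_var
    sd = np.sqrt(var)
    return CurveEstimate(
        grid=grid,
        mean=mean,
        sd=sd,
        lower3=mean - k_sigma * sd,
        upper3=mean + k_sigma * sd,
        k_sigma=k_sigma,
    )


def baseline_band(
    baseline: HRBaseline,
    grid: np.ndarray,
    k_sigma: float = 3.0,
    include_noise: bool = False,
) -> CurveEstimate:
    """Functional mean with a +/- k_sigma * sd band on a grid.

    By default the band covers the latent curve only (between-day pattern
    variation); ``include_noise=True`` widens it by the measurement-noise
    variance to cover raw observations.
    """
    return _band(
        baseline.coef_mean,
        baseline.coef_cov,
        baseline.basis,
        grid,
        k_sigma,
        baseline.noise_var,
        include_noise,
    )


# --- serialization ---------------------------------------------------------


def baseline_to_dict(baseline: HRBaseline) -> dict:
    b = baseline.basis
    return {
        "basis": {
            "n_basis": b.n_basis,
            "order": b.order,
            "knots": b.knots.tolist(),
            "domain": [b.domain.t_start, b.domain.t_end],
        },
        "coef_mean": baseline.coef_mean.tolist(),
        "coef_cov": baseline.coef_cov.tolist(),
        "coef_cov_raw": baseline.coef_cov_raw.tolist(),
        "sample_cov": baseline.sample_cov.tolist(),
        "noise_var": baseline.noise_var,
        "n_days": baseline.n_days,
        "excluded_days": [[d, r] for d, r in baseline.excluded_days],
    }


def baseline_from_dict(doc: dict) -> HRBaseline:
    bd = doc["basis"]
    domain = TimeDomain(*bd["domain"])
    basis = BasisSystem(
        n_basis=int(bd["n_basis"]),
        order=int(bd["order"]),
        knots=np.asarray(bd["knots"], dtype=float),
        domain=domain,
    )
    return HRBaseline(
        coef_mean=np.asarray(doc["coef_mean"], dtype=float),
        coef_cov=np.asarray(doc["coef_cov"], dtype=float),
        coef_cov_raw=np.asarray(doc["coef_cov_raw"], dtype=float),
        sample_cov=np.asarray(doc["sample_cov"], dtype=float),
        noise_var=float(doc["noise_var"]),
        n_days=int(doc["n_days"]),
        basis=basis,
        excluded_days=[(int(d), str(r)) for d, r in doc["excluded_days"]],
    )


def save_baseline(baseline: HRBaseline, path: str | Path) -> None:
    Path(path).write_text(json.dumps(baseline_to_dict(baseline), indent=1))


def load_baseline(path: str | Path) -> HRBaseline:
    return baseline_from_dict(json.loads(Path(path).read_text()))
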