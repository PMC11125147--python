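"""B-spline basis systems and per-day least-squares coefficient fitting.

A day's heart-rate trace is modelled as a smooth curve expanded in a fixed
basis, ``x(t) = Phi(t)^T C``, observed with i.i.d. Gaussian measurement
noise:

    y_{i,j} = x(t_{i,j}) + eps_{i,j},   eps_{i,j} ~ N(0, sigma^2).

This module builds the basis (clamped B-splines with uniform interior
knots on the diurnal domain [0, 24] h), evaluates the P x N basis kernel
matrix at arbitrary timestamps, and fits one coefficient vector per day by
ordinary least squares, exposing the hat-matrix diagnostics needed by the
pooled noise-variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "TimeDomain",
    "DayRecord",
    "BasisSystem",
    "BasisMatrix",
    "DayFit",
    "ModelConfig",
    "build_basis",
    "evaluate_basis",
    "fit_day",
    "estimate_noise_variance",
]

#: relative condition-number threshold above which the per-day Gram matrix
#: Phi Phi^T is treated as numerically singular
GRAM_COND_THRESHOLD = 1e10

#: days whose residual degrees of freedom trace(I - H) fall at or below this
#: guard are excluded from the pooled noise-variance estimate
DOF_GUARD = 0.5


class InvalidConfigurationError(ValueError):
    """A model or basis configuration violates its preconditions."""


class DomainError(ValueError):
    """A timestamp lies outside the basis domain."""


@dataclass(frozen=True)
class TimeDomain:
    """Closed time interval on which curves live, in hours since midnight."""

    t_start: float = 0.0
    t_end: float = 24.0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidConfigurationError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    def check(self, timestamps: np.ndarray) -> None:
        t = np.asarray(timestamps, dtype=float)
        if t.size == 0:
            return
        bad = (t < self.t_start) | (t > self.t_end) | ~np.isfinite(t)
        if bad.any():
            offender = t[bad][0]
            raise DomainError(
                f"timestamp {offender!r} outside domain "
                f"[{self.t_start}, {self.t_end}]"
            )


@dataclass(frozen=True)
class DayRecord:
    """One day's irregular (timestamp, HR) measurement vectors.

    Timestamps are canonicalized to ascending order on construction (a
    stable sort, so exact duplicates keep their relative order). Values are
    in beats per minute.
    """

    day_index: int
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("timestamps and values must be 1-d and equal length")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "timestamps", t[order])
        object.__setattr__(self, "values", y[order])

    @property
    def n_obs(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class BasisSystem:
    """A set of P basis functions on a time domain.

    Only B-splines ship; the (knots, order) parameterization is the
    standard clamped form: boundary knots repeated ``order`` times with
    ``n_basis - order`` uniformly spaced interior knots, so the functions
    form a partition of unity on the whole closed domain.
    """

    n_basis: int
    order: int
    knots: np.ndarray
    domain: TimeDomain
    kind: str = "bspline"

    @property
    def degree(self) -> int:
        return self.order - 1


@dataclass(frozen=True)
class BasisMatrix:
    """The P x N basis kernel matrix Phi(T) with entry (p, j) = phi_p(t_j)."""

    matrix: np.ndarray
    timestamps: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class DayFit:
    """Per-day least-squares fit: coefficients, residuals and diagnostics.

    ``gram_inverse`` is (Phi Phi^T)^-1 (pseudo-inverse when rank-deficient);
    it enters the debiasing term of the coefficient-covariance estimator.
    ``dof`` is the residual degrees of freedom trace(I - H).
    """

    day_index: int
    coefficients: np.ndarray
    residuals: np.ndarray
    hat_trace: float
    dof: float
    gram_inverse: np.ndarray
    n_obs: int
    rank_ok: bool
    gram_cond: float = float("inf")


@dataclass(frozen=True)
class ModelConfig:
    """Model-block configuration shared by the fitting pipeline."""

    n_basis: int = 13
    spline_order: int = 4
    ridge: float = 0.0
    min_obs_per_day: int | None = None  # None -> n_basis + 2
    t_period: float = 24.0
    #: days whose Gram condition number exceeds this are excluded from
    #: baseline pooling: a gap covering most of a basis function's support
    #: leaves that coefficient statistically unidentified long before the
    #: matrix is numerically singular
    max_day_gram_cond: float = 1e6

    def __post_init__(self) -> None:
        if self.ridge < 0:
            raise InvalidConfigurationError("ridge must be >= 0")
        if self.t_period <= 0:
            raise InvalidConfigurationError("t_period must be positive")

    @property
    def min_obs(self) -> int:
        if self.min_obs_per_day is None:
            return self.n_basis + 2
        return self.min_obs_per_day

    def make_basis(self) -> BasisSystem:
        return build_basis(
            self.n_basis, self.spline_order, TimeDomain(0.0, self.t_period)
        )


def build_basis(
    n_basis: int, order: int, domain: TimeDomain | None = None
) -> BasisSystem:
    """Construct a clamped B-spline basis with uniform interior knots.

    Parameters
    ----------
    n_basis
        Number of basis functions P.
    order
        Spline order (degree + 1); 4 gives cubic splines.
    domain
        Time domain; defaults to the diurnal [0, 24] h interval.
    """
    domain = domain or TimeDomain()
    if order < 1:
        raise InvalidConfigurationError("order must be >= 1")
    if n_basis < order:
        raise InvalidConfigurationError(
            f"n_basis ({n_basis}) must be >= order ({order})"
        )
    n_interior = n_basis - order
    interior = np.linspace(domain.t_start, domain.t_end, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [
            np.full(order, domain.t_start),
            interior,
            np.full(order, domain.t_end),
        ]
    )
    return BasisSystem(n_basis=n_basis, order=order, knots=knots, domain=domain)


def evaluate_basis(basis: BasisSystem, timestamps: np.ndarray) -> BasisMatrix:
    """Evaluate the basis kernel matrix Phi(T) at given timestamps.

    Returns the P x N matrix with entry (p, j) = phi_p(t_j). Timestamps must
    lie inside the closed domain; the right endpoint is included.
    """
    t = np.atleast_1d(np.asarray(timestamps, dtype=float))
    basis.domain.check(t)
    if t.size == 0:
        return BasisMatrix(matrix=np.zeros((basis.n_basis, 0)), timestamps=t)
    design = BSpline.design_matrix(
        t, basis.knots, basis.degree, extrapolate=False
    ).toarray()
    return BasisMatrix(matrix=design.T, timestamps=t)


def fit_day(basis: BasisSystem, day: DayRecord, ridge: float = 0.0) -> DayFit:
    """Fit one day's coefficients by (optionally ridge-stabilized) least squares.

    Solves the normal equations C-hat = (Phi Phi^T + ridge I)^-1 Phi Y. When
    ridge is zero and the Gram matrix is numerically singular (relative
    condition number above 1e10), the minimum-norm least-squares solution is
    returned and the fit flagged with ``rank_ok=False`` instead of raising.
    """
    if ridge < 0:
        raise InvalidConfigurationError("ridge must be >= 0")
    if day.n_obs == 0:
        raise ValueError(f"day {day.day_index} has no observations")
    phi = evaluate_basis(basis, day.timestamps).matrix  # P x N
    y = day.values
    gram = phi @ phi.T
    if ridge > 0:
        gram = gram + ridge * np.eye(basis.n_basis)

    # condition check on the (symmetric PSD) Gram matrix via its eigenvalues
    eigvals = np.linalg.eigvalsh((gram + gram.T) / 2.0)
    lam_max = float(eigvals[-1])
    lam_min = float(eigvals[0])
    rank_ok = lam_max > 0 and lam_min > lam_max / GRAM_COND_THRESHOLD
    gram_cond = lam_max / lam_min if lam_min > 0 else float("inf")

    if rank_ok or ridge > 0:
        coef = np.linalg.solve(gram, phi @ y)
        gram_inv = np.linalg.inv(gram)
    else:
        # minimum-norm pseudo-solution for degenerate days
        coef, *_ = np.linalg.lstsq(phi.T, y, rcond=None)
        gram_inv = np.linalg.pinv(gram)

    fitted = phi.T @ coef
    residuals = y - fitted
    # trace(H) = trace(Phi^T G^+ Phi) = sum over entries of (G^+ Phi) * Phi
    hat_trace = float(np.sum((gram_inv @ phi) * phi))
    dof = day.n_obs - hat_trace
    return DayFit(
        day_index=day.day_index,
        coefficients=coef,
        residuals=residuals,
        hat_trace=hat_trace,
        dof=dof,
        gram_inverse=gram_inv,
        n_obs=day.n_obs,
        rank_ok=bool(rank_ok),
        gram_cond=gram_cond,
    )


def hat_matrix(basis: BasisSystem, timestamps: np.ndarray) -> np.ndarray:
    """The N x N projection H = Phi^T (Phi Phi^T)^-1 Phi onto the basis span."""
    phi = evaluate_basis(basis, timestamps).matrix
    gram = phi @ phi.T
    return phi.T @ np.linalg.solve(gram, phi)


def estimate_noise_variance(fits: list[DayFit]) -> float:
    """Pooled unbiased estimate of the measurement-noise variance sigma^2.

    Averages eps_i^T eps_i / trace(I - H_i) over days; days with residual
    degrees of freedom at or below the guard (0.5) carry no information about
    sigma^2 and are excluded.
    """
    ratios = [
        float(f.residuals @ f.residuals) / f.dof for f in fits if f.dof > DOF_GUARD
    ]
    if not ratios:
        raise ValueError(
            "no day has positive residual degrees of freedom; "
            "cannot estimate the noise variance"
        )
    return float(np.mean(ratios))
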