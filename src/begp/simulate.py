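"""Seeded synthetic wearable heart-rate data.

Emulates the structure of multi-day wrist-sensor HR collection so the whole
pipeline is testable without subject data:

* a smooth diurnal truth pattern (low nocturnal HR, daytime elevation),
* day-to-day variation of the pattern via a coefficient covariance,
* i.i.d. Gaussian measurement noise on a noisy "PPG-like" sensor,
* sporadic motion-artifact shocks on that sensor,
* missingness as contiguous time blocks (device charging, removal), and
* a paired dense low-noise "ECG-like" sensor serving as ground truth.

All randomness flows from a single seed through independent child streams
(coefficients, noise, artifacts, missingness, ground-truth sensor), so
toggling one mechanism does not perturb the others under the same seed.

Defaults mirror desk-scale versions of the observed collection conditions:
about two weeks of data per subject, roughly a quarter of each day missing
in blocks of around an hour, and a noisy sensor with a few-bpm noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import BasisSystem, DayRecord, evaluate_basis

__all__ = [
    "SimConfig",
    "SimDataset",
    "make_diurnal_truth",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; rates are fractions of samples, sds in bpm."""

    n_days: int = 15
    samples_per_day: int = 1440  # 1-minute resolution over 24 h
    noise_sd: float = 3.0
    coef_true: np.ndarray | None = None  # drawn by make_diurnal_truth if None
    coef_cov_true: np.ndarray | None = None
    artifact_rate: float = 0.05
    artifact_sd: float = 25.0
    artifact_positive_bias: bool = False
    missing_rate: float = 0.25
    missing_block_hours: float = 1.0
    missing_mode: str = "block"  # "uniform" exists for tests only
    ecg_noise_sd: float = 1.0
    ecg_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("artifact_rate", "missing_rate", "ecg_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_sd", "artifact_sd", "ecg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.missing_rate >= 0.98:
            raise ValueError(
                "missing_rate >= 0.98 leaves nothing to fit; refusing"
            )
        if self.missing_mode not in ("block", "uniform"):
            raise ValueError("missing_mode must be 'block' or 'uniform'")


@dataclass(frozen=True)
class SimDataset:
    """One synthetic subject: noisy sensor days, truth, and bookkeeping."""

    days: list[DayRecord]  # noisy, gappy PPG-like sensor
    ground_truth_days: list[DayRecord]  # dense, low-noise ECG-like sensor
    day_coefs: np.ndarray  # M x P true per-day coefficients
    grid: np.ndarray  # the dense sampling grid (hours)
    truth_values: np.ndarray  # M x n true curve on the grid
    missing_mask: np.ndarray  # M x n, True where the noisy sensor lost data
    artifact_mask: np.ndarray  # M x n, True where a shock was injected
    block_log: list[int]  # per-day count of maximal gaps >= 2 samples
    basis: BasisSystem
    config: SimConfig

    def truth(self, day_index: int, t: np.ndarray) -> np.ndarray:
        """Evaluate day ``day_index``'s true curve at arbitrary times."""
        phi = evaluate_basis(self.basis, t).matrix
        return phi.T @ self.day_coefs[day_index - 1]

    @property
    def realized_missing_rate(self) -> float:
        return float(self.missing_mask.mean())


def _diurnal_template(t: np.ndarray) -> np.ndarray:
    """A plausible older-adult diurnal HR profile (bpm) on hours in [0, 24]."""
    return (
        60.0
        + 20.0 * np.exp(-0.5 * ((t - 14.0) / 4.0) ** 2)
        + 6.0 * np.exp(-0.5 * ((t - 8.5) / 1.8) ** 2)
        - 3.0 * np.exp(-0.5 * ((t - 3.0) / 2.0) ** 2)
    )


def make_diurnal_truth(
    basis: BasisSystem, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a subject's true mean coefficients and coefficient covariance.

    The mean curve is a smooth diurnal template (nocturnal trough near
    57 bpm, afternoon peak near 82 bpm) projected onto the basis, plus a
    small seeded subject-specific perturbation. The covariance is a smooth
    kernel over neighbouring coefficients scaled so the curve-level
    between-day sd is a few bpm everywhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E37]))
    dense = np.linspace(basis.domain.t_start, basis.domain.t_end, 2001)
    phi = evaluate_basis(basis, dense).matrix  # P x G
    target = _diurnal_template(
        (dense - basis.domain.t_start)
        / (basis.domain.t_end - basis.domain.t_start)
        * 24.0
    )
    coef_base, *_ = np.linalg.lstsq(phi.T, target, rcond=None)
    # subjects differ mainly in level (resting HR spans tens of bpm across
    # older adults) and mildly in shape; the level offset is projected back
    # into the plausible envelope so every subject's curve stays physiological
    offset = rng.normal(0.0, 7.0)
    shape = rng.normal(0.0, 2.0, size=basis.n_basis)
    curve = phi.T @ (coef_base + shape)
    lo, hi = 47.0 - float(curve.min()), 108.0 - float(curve.max())
    offset = float(np.clip(offset, min(lo, hi), max(lo, hi)))
    coef_true = coef_base + shape + offset

    p = basis.n_basis
    idx = np.arange(p)
    kernel = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / 2.0) ** 2)
    # scale so the pointwise curve sd averages ~3 bpm
    raw_var = np.einsum("pg,pq,qg->g", phi, kernel, phi)
    scale = 3.0**2 / float(np.mean(raw_var))
    coef_cov_true = scale * kernel
    return coef_true, coef_cov_true


def _block_missing_mask(
    n: int, target_missing: int, mean_block_samples: float, rng: np.random.Generator
) -> np.ndarray:
    """Delete contiguous blocks (exponential lengths) until the target count
    of missing samples is reached; the final block is truncated at the
    target so the realized rate matches the configured one."""
    mask = np.zeros(n, dtype=bool)
    while mask.sum() < target_missing:
        length = max(1, int(round(rng.exponential(mean_block_samples))))
        start = int(rng.integers(0, n))
        end = min(n, start + length)
        block = np.arange(start, end)
        new = block[~mask[block]]
        overshoot = int(mask.sum()) + new.size - target_missing
        if overshoot > 0:
            new = new[: new.size - overshoot]
        mask[new] = True
    return mask


def _count_gaps(mask: np.ndarray, min_len: int = 2) -> int:
    """Number of maximal missing runs of at least ``min_len`` samples."""
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    return int(np.sum((ends - starts) >= min_len))


def simulate_dataset(config: SimConfig, basis: BasisSystem) -> SimDataset:
    """Generate one subject's multi-day paired-sensor dataset.

    Per day i: draw coefficients C_i ~ N(coef_true, coef_cov_true); the true
    curve is x_i(t) = Phi(t)^T C_i on a uniform grid; the noisy sensor adds
    i.i.d. Gaussian noise plus Bernoulli motion-artifact shocks and then
    loses contiguous blocks of samples; the ground-truth sensor adds light
    noise with independent, lighter missingness and no artifacts.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_coef, s_noise, s_art, s_miss, s_ecg) = ss.spawn(5)
    rng_coef = np.random.default_rng(s_coef)
    rng_noise = np.random.default_rng(s_noise)
    rng_art = np.random.default_rng(s_art)
    rng_miss = np.random.default_rng(s_miss)
    rng_ecg = np.random.default_rng(s_ecg)

    if config.coef_true is None or config.coef_cov_true is None:
        ct, cc = make_diurnal_truth(basis, config.seed)
        config = replace(
            config,
            coef_true=ct if config.coef_true is None else config.coef_true,
            coef_cov_true=(
                cc if config.coef_cov_true is None else config.coef_cov_true
            ),
        )
    coef_true = np.asarray(config.coef_true, dtype=float)
    coef_cov_true = np.asarray(config.coef_cov_true, dtype=float)

    m, n = config.n_days, config.samples_per_day
    span = basis.domain.t_end - basis.domain.t_start
    grid = basis.domain.t_start + (np.arange(n) + 0.5) * span / n
    phi = evaluate_basis(basis, grid).matrix  # P x n
    dt_hours = span / n
    mean_block_samples = max(config.missing_block_hours / dt_hours, 1.0)

    # eigendecomposition-based square root tolerates a PSD (singular) cov
    w, v = np.linalg.eigh((coef_cov_true + coef_cov_true.T) / 2.0)
    chol = v * np.sqrt(np.clip(w, 0.0, None))

    day_coefs = coef_true + rng_coef.standard_normal((m, basis.n_basis)) @ chol.T
    truth_values = day_coefs @ phi  # M x n

    noisy = truth_values + config.noise_sd * rng_noise.standard_normal((m, n))
    artifact_mask = rng_art.random((m, n)) < config.artifact_rate
    shocks = config.artifact_sd * rng_art.standard_normal((m, n))
    if config.artifact_positive_bias:
        shocks = np.abs(shocks)
    noisy = noisy + artifact_mask * shocks

    target_missing = int(round(config.missing_rate * n))
    missing_mask = np.zeros((m, n), dtype=bool)
    for i in range(m):
        if target_missing == 0:
            continue
        if config.missing_mode == "block":
            missing_mask[i] = _block_missing_mask(
                n, target_missing, mean_block_samples, rng_miss
            )
        else:
            drop = rng_miss.choice(n, size=target_missing, replace=False)
            missing_mask[i, drop] = True
    block_log = [_count_gaps(missing_mask[i]) for i in range(m)]

    ecg_values = truth_values + config.ecg_noise_sd * rng_ecg.standard_normal((m, n))
    ecg_target = int(round(config.ecg_missing_rate * n))
    ecg_missing = np.zeros((m, n), dtype=bool)
    for i in range(m):
        if ecg_target > 0:
            ecg_missing[i] = _block_missing_mask(
                n, ecg_target, mean_block_samples, rng_ecg
            )

    days = [
        DayRecord(
            day_index=i + 1,
            timestamps=grid[~missing_mask[i]],
            values=noisy[i, ~missing_mask[i]],
        )
        for i in range(m)
    ]
    ground_truth_days = [
        DayRecord(
            day_index=i + 1,
            timestamps=grid[~ecg_missing[i]],
            values=ecg_values[i, ~ecg_missing[i]],
        )
        for i in range(m)
    ]
    return SimDataset(
        days=days,
        ground_truth_days=ground_truth_days,
        day_coefs=day_coefs,
        grid=grid,
        truth_values=truth_values,
        missing_mask=missing_mask,
        artifact_mask=artifact_mask,
        block_log=block_log,
        basis=basis,
        config=config,
    )


def _to_frame(days: list[DayRecord], subject_id: str) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "subject_id": subject_id,
                "day": d.day_index,
                "time_hours": d.timestamps,
                "hr_bpm": d.values,
            }
        )
        for d in days
    ]
    return pd.concat(frames, ignore_index=True)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # shortest round-trip float formatting so read-back is bit-identical
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def write_dataset(
    sim: SimDataset, out_dir: str | Path, subject_id: str = "S1"
) -> dict[str, Path]:
    """Write the long-format CSVs (noisy sensor, ground-truth sensor, truth
    curve) plus a manifest with realized rates; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppg": out / "ppg.csv",
        "ecg": out / "ecg.csv",
        "truth": out / "truth.csv",
        "manifest": out / "manifest.json",
    }
    try:
        _write_csv(_to_frame(sim.days, subject_id), paths["ppg"])
        _write_csv(_to_frame(sim.ground_truth_days, subject_id), paths["ecg"])
        m = sim.config.n_days
        truth_days = [
            DayRecord(i + 1, sim.grid, sim.truth_values[i]) for i in range(m)
        ]
        _write_csv(_to_frame(truth_days, subject_id), paths["truth"])
    except OSError as err:
        raise OSError(f"failed writing dataset under {out}: {err}") from err
    manifest = {
        "subject_id": subject_id,
        "seed": sim.config.seed,
        "n_days": m,
        "samples_per_day": sim.config.samples_per_day,
        "realized_missing_rate": sim.realized_missing_rate,
        "configured_missing_rate": sim.config.missing_rate,
        "artifact_rate": sim.config.artifact_rate,
        "noise_sd": sim.config.noise_sd,
        "block_gap_counts": sim.block_log,
        "n_rows_ppg": int((~sim.missing_mask).sum()),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
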