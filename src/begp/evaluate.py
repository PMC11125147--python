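"""Benchmark comparison of HR estimation methods with leave-one-day-out scoring.

Five estimators of a test day's true HR (scored against a ground-truth
sensor) are compared by mean squared error and error standard deviation:

  A  raw noisy-sensor measurements (nearest available sample);
  B  population mean — the grand mean of every subject's historical values;
  C  subject-specific mean of the historical values;
  D  the subject's baseline functional mean;
  E  the calibrated functional mean — the baseline posterior-updated with
     the test day's noisy measurements (the method under study).

The protocol is leave-one-day-out: for each candidate test day the baseline
is fit on the subject's remaining days, calibration uses the test day's
noisy data (never the ground-truth sensor), and all methods are scored on
the identical set of matched test points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline import HRBaseline, InsufficientDataError, baseline_mean, estimate_baseline
from .basis import DayRecord, ModelConfig
from .calibrate import CalibratedPosterior, calibrate, posterior_mean

__all__ = [
    "MethodResult",
    "BenchmarkTable",
    "SubjectData",
    "EvalConfig",
    "method_a_raw",
    "method_b_population_mean",
    "method_c_subject_mean",
    "method_d_functional_mean",
    "method_e_calibrated",
    "leave_one_day_out",
]

METHODS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class MethodResult:
    """Errors of one method against ground truth on a set of test points."""

    method_id: str
    estimates: np.ndarray
    errors: np.ndarray  # estimate - truth
    mse: float
    error_sd: float
    n_test: int

    @classmethod
    def from_errors(
        cls, method_id: str, estimates: np.ndarray, errors: np.ndarray
    ) -> "MethodResult":
        errors = np.asarray(errors, dtype=float)
        n = errors.size
        mse = float(np.mean(errors**2)) if n else float("nan")
        sd = float(np.std(errors, ddof=1)) if n >= 2 else float("nan")
        return cls(
            method_id=method_id,
            estimates=np.asarray(estimates, dtype=float),
            errors=errors,
            mse=mse,
            error_sd=sd,
            n_test=n,
        )


@dataclass(frozen=True)
class SubjectData:
    """One subject's paired sensors: noisy history and ground-truth days."""

    subject_id: str
    noisy_days: list[DayRecord]
    truth_days: list[DayRecord]


@dataclass(frozen=True)
class EvalConfig:
    """Benchmark settings on top of the shared model configuration."""

    model: ModelConfig = field(default_factory=ModelConfig)
    max_gap_hours: float = 5.0 / 60.0  # test points farther than this from
    # any noisy sample are dropped from every method identically
    min_days: int = 3
    population_weighting: str = "observation"  # or "subject"


@dataclass
class BenchmarkTable:
    """Per-subject and pooled (overall) method results."""

    per_subject: dict[str, dict[str, MethodResult]]
    overall: dict[str, MethodResult]
    skipped_subjects: dict[str, str] = field(default_factory=dict)


def _nearest_values(
    source: DayRecord, query_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Value at the nearest source timestamp for each query time, plus the
    absolute time gap to that nearest sample."""
    obs_t = source.timestamps
    obs_y = source.values
    idx = np.searchsorted(obs_t, query_times)
    left = np.clip(idx - 1, 0, obs_t.size - 1)
    right = np.clip(idx, 0, obs_t.size - 1)
    use_right = np.abs(obs_t[right] - query_times) < np.abs(
        obs_t[left] - query_times
    )
    nearest = np.where(use_right, right, left)
    return obs_y[nearest], np.abs(obs_t[nearest] - query_times)


def method_a_raw(noisy_day: DayRecord, test: DayRecord) -> MethodResult:
    """Raw noisy-sensor values looked up at the nearest available timestamp."""
    if noisy_day.n_obs == 0:
        raise ValueError("method A requires a nonempty noisy day")
    est, _ = _nearest_values(noisy_day, test.timestamps)
    return MethodResult.from_errors("A", est, est - test.values)


def _constant_method(
    method_id: str, history_values: np.ndarray, test: DayRecord
) -> MethodResult:
    if history_values.size == 0:
        raise ValueError(f"method {method_id} requires nonempty history")
    scalar = float(np.mean(history_values))
    est = np.full(test.n_obs, scalar)
    return MethodResult.from_errors(method_id, est, est - test.values)


def method_b_population_mean(
    all_subjects_history: list[np.ndarray] | np.ndarray,
    test: DayRecord,
    weighting: str = "observation",
) -> MethodResult:
    """Grand mean of all subjects' historical values as a constant estimate.

    ``weighting='observation'`` pools raw values with equal weight per
    observation; ``'subject'`` averages the per-subject means.
    """
    if isinstance(all_subjects_history, np.ndarray):
        all_subjects_history = [all_subjects_history]
    arrays = [np.asarray(a, dtype=float) for a in all_subjects_history if len(a)]
    if not arrays:
        raise ValueError("method B requires nonempty history")
    if weighting == "subject":
        pooled = np.array([a.mean() for a in arrays])
    else:
        pooled = np.concatenate(arrays)
    return _constant_method("B", pooled, test)


def method_c_subject_mean(
    subject_history: np.ndarray, test: DayRecord
) -> MethodResult:
    """Subject-specific mean of historical values as a constant estimate."""
    return _constant_method("C", np.asarray(subject_history, dtype=float), test)


def method_d_functional_mean(
    baseline: HRBaseline, test: DayRecord
) -> MethodResult:
    """The baseline functional mean evaluated at the test timestamps."""
    est = baseline_mean(baseline, test.timestamps)
    return MethodResult.from_errors("D", est, est - test.values)


def method_e_calibrated(
    posterior: CalibratedPosterior, test: DayRecord
) -> MethodResult:
    """The calibrated functional mean evaluated at the test timestamps."""
    est = posterior_mean(posterior, test.timestamps)
    return MethodResult.from_errors("E", est, est - test.values)


def _pool(method_id: str, results: list[MethodResult]) -> MethodResult:
    est = np.concatenate([r.estimates for r in results]) if results else np.array([])
    err = np.concatenate([r.errors for r in results]) if results else np.array([])
    return MethodResult.from_errors(method_id, est, err)


def leave_one_day_out(
    subject_data: list[SubjectData], config: EvalConfig | None = None
) -> BenchmarkTable:
    """Run the leave-one-day-out benchmark over all subjects.

    For each subject with at least ``min_days`` noisy days and any
    ground-truth day: every day with both sensors serves once as the test
    day; the baseline is fit on the remaining noisy days; calibration uses
    the test day's noisy data; all five methods are scored against the
    ground-truth sensor on the test points that have a noisy sample within
    ``max_gap_hours`` (the same set for every method). Subjects that cannot
    be evaluated are skipped with a logged reason.
    """
    config = config or EvalConfig()
    basis = config.model.make_basis()
    per_subject: dict[str, dict[str, MethodResult]] = {}
    skipped: dict[str, str] = {}
    collected: dict[str, list[MethodResult]] = {m: [] for m in METHODS}

    all_values = {
        s.subject_id: {d.day_index: d.values for d in s.noisy_days}
        for s in subject_data
    }

    for subject in subject_data:
        sid = subject.subject_id
        if len(subject.noisy_days) < config.min_days:
            skipped[sid] = (
                f"only {len(subject.noisy_days)} days (< {config.min_days})"
            )
            continue
        truth_by_day = {d.day_index: d for d in subject.truth_days}
        noisy_by_day = {d.day_index: d for d in subject.noisy_days}
        test_days = sorted(set(truth_by_day) & set(noisy_by_day))
        if not test_days:
            skipped[sid] = "no ground-truth sensor data"
            continue

        per_day_results: dict[str, list[MethodResult]] = {m: [] for m in METHODS}
        any_scored = False
        for test_idx in test_days:
            noisy_test = noisy_by_day[test_idx]
            truth_full = truth_by_day[test_idx]
            if noisy_test.n_obs == 0 or truth_full.n_obs == 0:
                continue
            # identical test set for all methods: keep truth points with a
            # noisy sample within the alignment gap
            _, gaps = _nearest_values(noisy_test, truth_full.timestamps)
            keep = gaps <= config.max_gap_hours
            if keep.sum() < 2:
                continue
            test = DayRecord(
                day_index=test_idx,
                timestamps=truth_full.timestamps[keep],
                values=truth_full.values[keep],
            )
            history = [d for d in subject.noisy_days if d.day_index != test_idx]
            try:
                baseline = estimate_baseline(history, basis, config.model)
            except InsufficientDataError:
                continue
            posterior = calibrate(baseline, noisy_test)

            subj_hist = np.concatenate(
                [all_values[sid][d.day_index] for d in history]
            )
            pop_hist = [
                np.concatenate(list(day_map.values()))
                for other, day_map in all_values.items()
                if other != sid
            ] + [subj_hist]

            per_day_results["A"].append(method_a_raw(noisy_test, test))
            per_day_results["B"].append(
                method_b_population_mean(
                    pop_hist, test, weighting=config.population_weighting
                )
            )
            per_day_results["C"].append(method_c_subject_mean(subj_hist, test))
            per_day_results["D"].append(method_d_functional_mean(baseline, test))
            per_day_results["E"].append(method_e_calibrated(posterior, test))
            any_scored = True

        if not any_scored:
            skipped[sid] = "no scoreable test day"
            continue
        per_subject[sid] = {
            m: _pool(m, per_day_results[m]) for m in METHODS
        }
        for m in METHODS:
            collected[m].extend(per_day_results[m])

    overall = {m: _pool(m, collected[m]) for m in METHODS}
    return BenchmarkTable(
        per_subject=per_subject, overall=overall, skipped_subjects=skipped
    )
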