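"""Kinematic brain-injury metrics and the evaluation harness.

Implemented metrics (all computed from a :class:`~impactkin.dataio.KinematicRecord`):

* ``hic15`` — head injury criterion: maximum over all sample-aligned windows
  ``(t1, t2)`` with ``0 < t2 - t1 <= 15 ms`` of
  ``(t2 - t1) * [mean resultant linear acceleration in g]^2.5`` (automotive
  standard formulation; g = 9.80665 m/s²).
* ``ric36`` — rotational injury criterion: the same functional applied to
  the resultant angular acceleration in rad/s² with a 36 ms window cap.
* ``bric`` — brain injury criterion: root-sum-square of per-axis peak
  angular velocities normalized by critical values, default
  (66.25, 56.45, 42.87) rad/s for coronal/sagittal/axial.
* ``bam`` — brain angle metric: a per-axis lumped brain–skull model
  ``I*theta'' + c*theta' + k*theta = -I*alpha(t)`` driven from rest by the
  head angular acceleration; the metric is the maximum over time of the
  resultant relative brain angle. The rotational inertia, stiffness and
  damping are required configuration — published lumped-model calibrations
  vary, so no silent defaults are provided.

Published 50%-risk thresholds: HIC15 240 (concussion) / 667 (skull
fracture), RIC36 10.3e6, BrIC 0.5. The accuracy of an approximated data set
is summarized by the percent error ``|approx - gt|/|gt| * 100`` per record,
a Friedman rank test across methods, and threshold-based
sensitivity/specificity against the ground-truth labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dataio
from .errors import ConfigError, DatasetValidationError, DegenerateDataWarning

__all__ = [
    "GRAVITY",
    "BRIC_CRITICAL_DEFAULT",
    "MetricThresholds",
    "BAMParams",
    "ClassificationReport",
    "hic15",
    "ric36",
    "bric",
    "bam",
    "metric_error",
    "metric_errors",
    "classify_and_confuse",
    "friedman_test",
    "compute_metrics",
    "evaluate_approximations",
]

GRAVITY = 9.80665  # m/s^2 per g
BRIC_CRITICAL_DEFAULT = (66.25, 56.45, 42.87)  # rad/s, coronal/sagittal/axial


@dataclass
class MetricThresholds:
    """Published 50%-risk thresholds, all overridable."""

    hic_concussion: float = 240.0
    hic_fracture: float = 667.0
    ric_concussion: float = 10.3e6
    bric_concussion: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hic_concussion", "hic_fracture", "ric_concussion",
                     "bric_concussion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def per_metric(self) -> dict[str, dict[str, float]]:
        return {
            "hic15": {
                "concussion": self.hic_concussion,
                "fracture": self.hic_fracture,
            },
            "ric36": {"concussion": self.ric_concussion},
            "bric": {"concussion": self.bric_concussion},
        }


@dataclass
class BAMParams:
    """Per-direction lumped brain–skull model parameters.

    ``inertia`` kg·m², ``stiffness`` N·m/rad, ``damping`` N·m·s/rad, each a
    3-tuple for (coronal, sagittal, axial). ``substeps`` subdivides the
    signal's sample step for the fixed-step RK4 integration.
    """

    inertia: tuple[float, float, float]
    stiffness: tuple[float, float, float]
    damping: tuple[float, float, float]
    substeps: int = 4

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.inertia) or any(
            v <= 0 for v in self.stiffness
        ):
            raise ConfigError("inertia and stiffness must be > 0")
        if any(v < 0 for v in self.damping):
            raise ConfigError("damping must be >= 0")
        if self.substeps < 1:
            raise ConfigError("substeps must be >= 1")


@dataclass
class ClassificationReport:
    """2x2 confusion counts with sensitivity/specificity."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos > 0 else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg > 0 else None


def _windowed_power_max(
    trace: np.ndarray, sample_rate: float, max_window_s: float
) -> float:
    """max over windows of (t2-t1) * [window-mean of trace]^2.5.

    ``trace`` must be non-negative (a resultant). Window endpoints are
    sample instants, the integral is trapezoidal, and the shortest window
    is one sample step.
    """
    m = trace.shape[0]
    if m < 2:
        raise DatasetValidationError("need at least 2 samples")
    dt = 1.0 / sample_rate
    # cumulative trapezoid integral, I[i] = integral over [t0, t_i]
    cumint = np.concatenate(
        [[0.0], np.cumsum(0.5 * (trace[1:] + trace[:-1]) * dt)]
    )
    w_max = min(int(round(max_window_s * sample_rate)), m - 1)
    best = 0.0
    for w in range(1, w_max + 1):
        span = w * dt
        avg = (cumint[w:] - cumint[:-w]) / span
        val = span * float(np.max(avg)) ** 2.5
        if val > best:
            best = val
    return best


def hic15(record: dataio.KinematicRecord, max_window_s: float = 0.015) -> float:
    """Head injury criterion over the resultant linear acceleration (g)."""
    a_res_g = dataio.resultant(record.lin_acc) / GRAVITY
    return _windowed_power_max(a_res_g, record.sample_rate, max_window_s)


def ric36(record: dataio.KinematicRecord, max_window_s: float = 0.036) -> float:
    """Rotational injury criterion over resultant angular acceleration."""
    alpha = dataio.derive_angular_acceleration(record)
    return _windowed_power_max(
        dataio.resultant(alpha), record.sample_rate, max_window_s
    )


def bric(
    record: dataio.KinematicRecord,
    critical_values: tuple[float, float, float] = BRIC_CRITICAL_DEFAULT,
) -> float:
    """Brain injury criterion from per-axis peak angular velocities."""
    crit = np.asarray(critical_values, dtype=float)
    if np.any(crit <= 0):
        raise ConfigError("critical angular velocities must be > 0")
    peaks = np.max(np.abs(record.ang_vel), axis=1)
    return float(np.sqrt(np.sum((peaks / crit) ** 2)))


def bam(record: dataio.KinematicRecord, params: BAMParams) -> float:
    """Maximum resultant relative brain angle (rad) from the lumped model.

    Integrates, per anatomical direction, the base-excitation oscillator
    ``theta'' = -alpha(t) - (c/I)*theta' - (k/I)*theta`` from rest with
    fixed-step RK4 at the signal's sample step divided by
    ``params.substeps``; the forcing is linearly interpolated between
    samples.
    """
    alpha = dataio.derive_angular_acceleration(record)
    m = record.n_samples
    dt = 1.0 / record.sample_rate
    sub = params.substeps
    h = dt / sub
    n_steps = (m - 1) * sub
    # forcing on the half-step grid used by the RK4 stages
    t_fine = np.arange(2 * n_steps + 1) * (h / 2.0)
    forcing = np.empty((3, t_fine.shape[0]))
    for d in range(3):
        forcing[d] = np.interp(t_fine, record.time, alpha[d])

    # equation normalized by I: theta'' + (c/I)th' + (k/I)th = -alpha
    c_over_I = np.array(params.damping) / np.array(params.inertia)
    k_over_I = np.array(params.stiffness) / np.array(params.inertia)

    theta = np.zeros(3)
    thdot = np.zeros(3)
    max_norm = 0.0

    def accel(th, thd, f):
        return -f - c_over_I * thd - k_over_I * th

    for s in range(n_steps):
        f0 = forcing[:, 2 * s]
        fh = forcing[:, 2 * s + 1]
        f1 = forcing[:, 2 * s + 2]
        k1v = accel(theta, thdot, f0)
        k1x = thdot
        k2v = accel(theta + 0.5 * h * k1x, thdot + 0.5 * h * k1v, fh)
        k2x = thdot + 0.5 * h * k1v
        k3v = accel(theta + 0.5 * h * k2x, thdot + 0.5 * h * k2v, fh)
        k3x = thdot + 0.5 * h * k2v
        k4v = accel(theta + h * k3x, thdot + h * k3v, f1)
        k4x = thdot + h * k3v
        theta = theta + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        thdot = thdot + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        norm = float(np.sqrt(np.sum(theta * theta)))
        if norm > max_norm:
            max_norm = norm
    if not np.isfinite(max_norm) or not np.all(np.isfinite(theta)):
        raise ConfigError(
            f"lumped-model integration diverged (|theta| -> {max_norm}); "
            f"check stiffness/damping/substeps"
        )
    return max_norm


def metric_error(approx_value: float, gt_value: float) -> float:
    """Percent error ``|approx - gt| / |gt| * 100``; undefined for gt = 0."""
    if gt_value == 0:
        raise ConfigError("percent error undefined for zero ground truth")
    return abs(approx_value - gt_value) / abs(gt_value) * 100.0


def metric_errors(
    approx_values: np.ndarray, gt_values: np.ndarray
) -> tuple[np.ndarray, int]:
    """Vectorized percent errors; zero-GT records are excluded and counted."""
    approx = np.asarray(approx_values, dtype=float)
    gt = np.asarray(gt_values, dtype=float)
    if approx.shape != gt.shape:
        raise DatasetValidationError("length mismatch")
    ok = gt != 0
    errs = np.abs(approx[ok] - gt[ok]) / np.abs(gt[ok]) * 100.0
    return errs, int(np.sum(~ok))


def classify_and_confuse(
    gt_values: np.ndarray, approx_values: np.ndarray, threshold: float
) -> ClassificationReport:
    """Threshold both series (label = value > threshold) and cross-tabulate.

    Ground-truth labels define the condition, approximation labels the
    prediction.
    """
    gt = np.asarray(gt_values, dtype=float)
    approx = np.asarray(approx_values, dtype=float)
    if gt.shape != approx.shape:
        raise DatasetValidationError("length mismatch")
    gt_pos = gt > threshold
    ap_pos = approx > threshold
    return ClassificationReport(
        tp=int(np.sum(gt_pos & ap_pos)),
        fp=int(np.sum(~gt_pos & ap_pos)),
        tn=int(np.sum(~gt_pos & ~ap_pos)),
        fn=int(np.sum(gt_pos & ~ap_pos)),
    )


def friedman_test(values: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across methods (columns) within records (rows).

    Uses within-row mid-ranks with the standard tie correction; the
    statistic is referred to a chi-squared law with ``k - 1`` degrees of
    freedom. Fully tied data (every row constant) is degenerate: a warning
    is emitted and ``(0.0, 1.0)`` returned.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ConfigError("values must be 2-D (records x methods)")
    n, k = X.shape
    if k < 2 or n < 2:
        raise ConfigError("need at least 2 methods and 2 records")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    # tie correction: sum over rows of (t^3 - t) for each tie group
    tie_sum = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1.0))
    if correction <= 0.0:
        warnings.warn(
            "all rows fully tied: Friedman statistic degenerate",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    col_ranksum = ranks.sum(axis=0)
    chi2 = (
        12.0 / (n * k * (k + 1.0)) * float(np.sum(col_ranksum**2))
        - 3.0 * n * (k + 1.0)
    ) / correction
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), p


def compute_metrics(
    dataset: dataio.KinematicDataset,
    metrics: tuple[str, ...] = ("hic15", "ric36", "bric"),
    bam_params: BAMParams | None = None,
    bric_critical: tuple[float, float, float] = BRIC_CRITICAL_DEFAULT,
) -> pd.DataFrame:
    """Per-record metric table for a data set."""
    funcs = {
        "hic15": hic15,
        "ric36": ric36,
        "bric": lambda r: bric(r, bric_critical),
        "bam": lambda r: bam(r, bam_params),
    }
    for name in metrics:
        if name not in funcs:
            raise ConfigError(f"unknown metric {name!r}")
        if name == "bam" and bam_params is None:
            raise ConfigError("bam requires explicit BAMParams")
    rows = []
    for rec in dataset:
        row: dict = {"record_id": rec.record_id}
        for name in metrics:
            row[name] = funcs[name](rec)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Aggregated accuracy report of approximations vs ground truth."""

    metric_values: dict[str, pd.DataFrame]  # method -> per-record table
    errors: pd.DataFrame  # metric, method, mean/median error, n_excluded
    friedman: pd.DataFrame  # metric, method, chi2, p, significant
    classification: pd.DataFrame  # metric, threshold, method, counts, rates
    alpha: float = 0.01
    thresholds: MetricThresholds = field(default_factory=MetricThresholds)


def evaluate_approximations(
    gt_dataset: dataio.KinematicDataset,
    approximations: dict[str, dataio.KinematicDataset],
    metrics: tuple[str, ...] = ("hic15", "ric36", "bric"),
    bam_params: BAMParams | None = None,
    thresholds: MetricThresholds | None = None,
    alpha: float = 0.01,
) -> EvaluationReport:
    """Full accuracy harness: metrics, percent errors, Friedman tests and
    threshold classification for each approximated data set against the
    ground truth. Approximations must be record-aligned with the GT set.
    """
    thresholds = thresholds or MetricThresholds()
    tables = {"gt": compute_metrics(gt_dataset, metrics, bam_params)}
    for name, ds in approximations.items():
        if len(ds) != len(gt_dataset):
            raise DatasetValidationError(
                f"approximation {name!r} is not record-aligned with GT"
            )
        tables[name] = compute_metrics(ds, metrics, bam_params)

    err_rows, fr_rows, cls_rows = [], [], []
    thr_map = thresholds.per_metric()
    for metric in metrics:
        gt_vals = tables["gt"][metric].to_numpy()
        for name in approximations:
            ap_vals = tables[name][metric].to_numpy()
            errs, n_excl = metric_errors(ap_vals, gt_vals)
            err_rows.append(
                {
                    "metric": metric,
                    "method": name,
                    "mean_error_pct": float(errs.mean()) if errs.size else np.nan,
                    "median_error_pct": float(np.median(errs)) if errs.size else np.nan,
                    "n_excluded": n_excl,
                }
            )
            chi2, p = friedman_test(np.column_stack([gt_vals, ap_vals]))
            fr_rows.append(
                {
                    "metric": metric,
                    "method": name,
                    "chi2": chi2,
                    "p": p,
                    "significant": p < alpha,
                }
            )
            for thr_name, thr in thr_map.get(metric, {}).items():
                rep = classify_and_confuse(gt_vals, ap_vals, thr)
                cls_rows.append(
                    {
                        "metric": metric,
                        "threshold": thr_name,
                        "threshold_value": thr,
                        "method": name,
                        "tp": rep.tp,
                        "fp": rep.fp,
                        "tn": rep.tn,
                        "fn": rep.fn,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity,
                    }
                )
    return EvaluationReport(
        metric_values=tables,
        errors=pd.DataFrame(err_rows),
        friedman=pd.DataFrame(fr_rows),
        classification=pd.DataFrame(cls_rows),
        alpha=alpha,
        thresholds=thresholds,
    )
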