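"""Stochastic emulator of head-impact kinematics from a truncated SVD basis.

New impact traces are produced as

    x* = sum_{i=1..k} sigma_i * y_i* * u_i,

where each modal score ``y_i*`` is drawn independently from a Gaussian with
the empirical mean and variance of the corresponding score vector ``y_i``
(the in-sample SVD scores are exactly uncorrelated, so independent marginals
are the minimal faithful sampling law; the Gaussian family matches the
observed score distributions of on-field data). A bootstrap alternative
(``scores='empirical'``) resamples the observed scores per mode for data
whose scores are visibly non-Gaussian.

Emulated populations are validated against the reference by two-sample
tests on physical features — peak magnitude, peak time, pulse duration —
and on the projections of the reference temporal modes onto both data sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import biphasic, pca
from .errors import ConfigError, DatasetValidationError, NoPulseError

__all__ = [
    "EmulatorModel",
    "FeatureComparison",
    "fit_emulator",
    "emulate",
    "synthesize_from_scores",
    "compare_features",
    "score_projections",
]


@dataclass
class EmulatorModel:
    """Truncated modal model: retained modes plus per-mode score laws."""

    k: int
    sigma: np.ndarray  # (k,)
    U: np.ndarray  # (m, k)
    score_mean: np.ndarray  # (k,)
    score_sd: np.ndarray  # (k,)
    scores: np.ndarray | None = None  # (n, k), kept for bootstrap sampling
    qoi: str = "ang_vel"
    direction: int = 0
    sample_rate: float = 1000.0
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if np.any(self.score_sd < 0):
            raise ConfigError("score standard deviations must be >= 0")

    def mean_trace(self) -> np.ndarray:
        """Expected emulated trace ``sum_i sigma_i*mean_i*u_i``."""
        return self.U @ (self.sigma * self.score_mean)


def fit_emulator(basis: pca.PCABasis, k: int) -> EmulatorModel:
    """Retain the first ``k`` modes and their empirical score statistics."""
    if not 1 <= k <= basis.r:
        raise ConfigError(f"k must be in [1, {basis.r}], got {k}")
    Yk = basis.Y[:, :k]
    return EmulatorModel(
        k=k,
        sigma=basis.sigma[:k].copy(),
        U=basis.U[:, :k].copy(),
        score_mean=Yk.mean(axis=0),
        score_sd=Yk.std(axis=0, ddof=1),
        scores=Yk.copy(),
        qoi=basis.qoi,
        direction=basis.direction,
        sample_rate=basis.sample_rate,
        n_fit=basis.n,
    )


def synthesize_from_scores(
    model: EmulatorModel, scores: np.ndarray
) -> np.ndarray:
    """Deterministic reconstruction ``U_k diag(sigma) scores^T``.

    ``scores`` has shape ``(n, k)``; feeding back the empirical score
    vectors reproduces the rank-``k`` reconstruction of the source matrix
    exactly.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != model.k:
        raise ConfigError(f"scores must be (n, {model.k})")
    return (model.U * model.sigma) @ scores.T


def emulate(
    model: EmulatorModel,
    n_new: int,
    seed: int,
    scores: str = "gaussian",
) -> pca.DataMatrix:
    """Draw ``n_new`` emulated traces.

    ``scores='gaussian'`` (default) samples each mode's score from
    ``Normal(mean_i, sd_i^2)`` independently; ``'empirical'`` bootstraps the
    observed scores per mode.
    """
    if n_new < 1:
        raise ConfigError("n_new must be >= 1")
    rng = np.random.default_rng(seed)
    if scores == "gaussian":
        Ystar = rng.normal(
            model.score_mean, model.score_sd, size=(n_new, model.k)
        )
    elif scores == "empirical":
        if model.scores is None:
            raise ConfigError("model carries no empirical scores")
        idx = rng.integers(0, model.scores.shape[0], size=(n_new, model.k))
        Ystar = model.scores[idx, np.arange(model.k)]
    else:
        raise ConfigError("scores must be 'gaussian' or 'empirical'")
    return pca.DataMatrix(
        values=synthesize_from_scores(model, Ystar),
        qoi=model.qoi,
        direction=model.direction,
        record_ids=[f"emulated{j:05d}" for j in range(n_new)],
        sample_rate=model.sample_rate,
    )


def _trace_features(X: pca.DataMatrix) -> pd.DataFrame:
    """Per-column peak magnitude, peak time and pulse duration.

    Pulse duration is measured on the acceleration-like signal: angular
    velocity columns are forward-differenced first, other QoIs are used
    directly. Columns with no detectable pulse get NaN duration.
    """
    vals = X.values
    fs = X.sample_rate
    peak_idx = np.argmax(np.abs(vals), axis=0)
    peak_mag = np.abs(vals[peak_idx, np.arange(vals.shape[1])])
    peak_time = peak_idx / fs
    durations = np.full(vals.shape[1], np.nan)
    for j in range(vals.shape[1]):
        trace = vals[:, j]
        if X.qoi == "ang_vel":
            a = np.diff(trace) * fs
            trace = np.concatenate([a, a[-1:]])
        try:
            durations[j] = biphasic.detect_pulse(trace, fs).dt
        except (NoPulseError, ConfigError):
            pass
    return pd.DataFrame(
        {
            "peak_magnitude": peak_mag,
            "peak_time": peak_time,
            "pulse_duration": durations,
        }
    )


@dataclass
class FeatureComparison:
    """Two-sample comparison of emulated vs reference feature distributions.

    ``table`` has one row per feature with summary statistics for both
    sides, the Kolmogorov–Smirnov statistic and its p-value.
    """

    table: pd.DataFrame
    alpha: float = 0.01

    def significant(self) -> list[str]:
        """Features that differ at the configured significance level."""
        t = self.table
        return list(t.loc[t["pvalue"] < self.alpha, "feature"])


def compare_features(
    emulated: pca.DataMatrix,
    reference: pca.DataMatrix,
    alpha: float = 0.01,
    n_modes: int = 3,
) -> FeatureComparison:
    """Compare emulated and reference populations feature by feature.

    Features: peak magnitude, peak time, pulse duration, and the
    projections of the first ``n_modes`` reference temporal modes onto the
    columns of both matrices. Each feature is tested with a two-sample
    Kolmogorov–Smirnov test.
    """
    if emulated.n == 0 or reference.n == 0:
        raise DatasetValidationError("both data sets must be non-empty")
    if emulated.sample_rate != reference.sample_rate:
        raise DatasetValidationError("sample rates differ")
    feats_e = _trace_features(emulated)
    feats_r = _trace_features(reference)
    basis = pca.decompose(reference)
    n_modes = min(n_modes, basis.r)
    for i in range(n_modes):
        u = basis.U[:, i]
        feats_e[f"mode{i + 1}_projection"] = u @ emulated.values
        feats_r[f"mode{i + 1}_projection"] = u @ reference.values
    rows = []
    for col in feats_r.columns:
        a = feats_r[col].dropna().to_numpy()
        b = feats_e[col].dropna().to_numpy()
        ks = stats.ks_2samp(a, b)
        rows.append(
            {
                "feature": col,
                "ref_mean": a.mean(),
                "ref_sd": a.std(ddof=1),
                "emu_mean": b.mean(),
                "emu_sd": b.std(ddof=1),
                "statistic": ks.statistic,
                "pvalue": ks.pvalue,
            }
        )
    return FeatureComparison(table=pd.DataFrame(rows), alpha=alpha)


def score_projections(basis: pca.PCABasis, k: int) -> dict[int, np.ndarray]:
    """Score pairs ``(y_1, y_j)`` for ``j = 2..k``.

    Returns a mapping ``j -> (n, 2)`` array of paired coordinates, the raw
    material for score scatter plots and distribution checks.
    """
    if k < 2:
        raise ConfigError("k must be >= 2 to form projections")
    if k > basis.r:
        raise ConfigError(f"k must be <= {basis.r}")
    y1 = basis.Y[:, 0]
    return {
        j: np.column_stack([y1, basis.Y[:, j - 1]]) for j in range(2, k + 1)
    }
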