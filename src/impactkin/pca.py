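"""Low-rank (PCA/SVD) representation of head-impact kinematics.

For one quantity of interest (QoI: linear acceleration, angular velocity, or
angular acceleration) in one anatomical direction, the data set is arranged
as a matrix ``X`` of shape ``(m, n)`` — ``m`` time steps per impact down the
rows, ``n`` impacts across the columns. The economy SVD

    X = U @ diag(sigma) @ Y.T

yields orthonormal temporal modes ``u_i`` (columns of U), singular values
``sigma_i`` in descending order, and orthonormal per-impact score vectors
``y_i`` (columns of Y). The matrix is factored directly, without mean
centering, so the first mode absorbs the mean impact shape; pass
``center=True`` to :func:`decompose` to explore the centered variant.

The reduction quality of a ``k``-mode truncation is measured by the
first-power singular-value fraction

    eta(k) = sum(sigma[:k]) / sum(sigma),

and ``min_modes`` returns the smallest ``k`` with ``eta(k) >= target``
(the standard working criterion is ``eta >= 0.90``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import dataio
from .errors import ConfigError, DatasetValidationError

__all__ = [
    "QOIS",
    "DataMatrix",
    "PCABasis",
    "assemble_data_matrix",
    "decompose",
    "energy_fraction",
    "min_modes",
    "reconstruct",
    "convergence_analysis",
    "build_pca_dataset",
]

QOIS = ("lin_acc", "ang_vel", "ang_acc")


@dataclass
class DataMatrix:
    """``(m, n)`` matrix of one QoI/direction; columns are impacts."""

    values: np.ndarray
    qoi: str = "ang_vel"
    direction: int = 0
    record_ids: list[str] | None = None
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("DataMatrix values must be 2-D (m x n)")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("DataMatrix contains non-finite entries")
        if self.qoi not in QOIS:
            raise ConfigError(f"qoi must be one of {QOIS}, got {self.qoi!r}")
        if self.direction not in (0, 1, 2):
            raise ConfigError("direction index must be 0, 1, or 2")
        if self.record_ids is None:
            self.record_ids = [f"col{j:04d}" for j in range(self.values.shape[1])]
        if len(self.record_ids) != self.values.shape[1]:
            raise ConfigError("record_ids length must equal column count")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class PCABasis:
    """Economy SVD factors of a :class:`DataMatrix`.

    ``U`` is ``(m, r)``, ``sigma`` length ``r`` descending, ``Y`` is
    ``(n, r)``, with ``r = min(m, n)``. A deterministic sign convention is
    applied: each temporal mode is flipped so its largest-magnitude element
    is positive (score vector flipped to match), making repeated
    decompositions bit-identical.
    """

    U: np.ndarray
    sigma: np.ndarray
    Y: np.ndarray
    qoi: str = "ang_vel"
    direction: int = 0
    sample_rate: float = 1000.0
    record_ids: list[str] = field(default_factory=list)
    centered: bool = False
    mean: np.ndarray | None = None

    @property
    def r(self) -> int:
        return self.sigma.shape[0]

    @property
    def m(self) -> int:
        return self.U.shape[0]

    @property
    def n(self) -> int:
        return self.Y.shape[0]


def assemble_data_matrix(
    dataset: dataio.KinematicDataset, qoi: str, direction: int
) -> DataMatrix:
    """Stack one QoI/direction trace per record into an ``(m, n)`` matrix.

    ``ang_acc`` is derived on the fly with the package's forward-difference
    rule; the other QoIs are copied verbatim.
    """
    if qoi not in QOIS:
        raise ConfigError(f"qoi must be one of {QOIS}, got {qoi!r}")
    if not len(dataset):
        raise DatasetValidationError("cannot assemble matrix from empty dataset")
    cols = []
    for rec in dataset:
        if qoi == "lin_acc":
            cols.append(rec.lin_acc[direction])
        elif qoi == "ang_vel":
            cols.append(rec.ang_vel[direction])
        else:
            cols.append(dataio.derive_angular_acceleration(rec)[direction])
    return DataMatrix(
        values=np.column_stack(cols),
        qoi=qoi,
        direction=direction,
        record_ids=[r.record_id for r in dataset],
        sample_rate=dataset.sample_rate,
    )


def decompose(X: DataMatrix, center: bool = False) -> PCABasis:
    """Economy SVD of the data matrix with a deterministic sign convention."""
    A = X.values
    mean = None
    if center:
        mean = A.mean(axis=1, keepdims=True)
        A = A - mean
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    Y = Vt.T
    # sign convention: largest-|.| element of each temporal mode positive
    idx = np.argmax(np.abs(U), axis=0)
    flip = np.sign(U[idx, np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    Y = Y * flip
    return PCABasis(
        U=U,
        sigma=s,
        Y=Y,
        qoi=X.qoi,
        direction=X.direction,
        sample_rate=X.sample_rate,
        record_ids=list(X.record_ids or []),
        centered=center,
        mean=None if mean is None else mean.ravel(),
    )


def energy_fraction(basis: PCABasis, k: int) -> float:
    """First-power singular-value fraction eta(k) captured by ``k`` modes."""
    if not 0 <= k <= basis.r:
        raise ConfigError(f"k must be in [0, {basis.r}], got {k}")
    total = float(basis.sigma.sum())
    if total == 0.0:
        raise ConfigError("zero matrix: eta(k) undefined")
    return float(basis.sigma[:k].sum()) / total


def min_modes(basis: PCABasis, eta_target: float) -> int:
    """Smallest ``k`` with ``eta(k) >= eta_target``."""
    if not 0.0 < eta_target <= 1.0:
        raise ConfigError(f"eta_target must be in (0, 1], got {eta_target}")
    total = float(basis.sigma.sum())
    if total == 0.0:
        raise ConfigError("zero matrix: eta(k) undefined")
    cum = np.cumsum(basis.sigma) / total
    # first index with cum >= target; clamp for eta_target == 1.0 when
    # cum[-1] rounds to just under 1
    k = int(np.searchsorted(cum, eta_target, side="left")) + 1
    return min(k, basis.r)


def reconstruct(basis: PCABasis, k: int) -> DataMatrix:
    """Rank-``k`` reconstruction ``sum_{i<=k} sigma_i u_i y_i^T``."""
    if not 1 <= k <= basis.r:
        raise ConfigError(f"k must be in [1, {basis.r}], got {k}")
    vals = (basis.U[:, :k] * basis.sigma[:k]) @ basis.Y[:, :k].T
    if basis.centered and basis.mean is not None:
        vals = vals + basis.mean[:, None]
    return DataMatrix(
        values=vals,
        qoi=basis.qoi,
        direction=basis.direction,
        record_ids=list(basis.record_ids) or None,
        sample_rate=basis.sample_rate,
    )


def convergence_analysis(
    dataset: dataio.KinematicDataset,
    subset_sizes: Sequence[int],
    n_repeats: int,
    eta_target: float,
    seed: int,
    qoi: str = "ang_vel",
    direction: int = 1,
) -> pd.DataFrame:
    """Minimal mode count as a function of data-set size.

    For each subset size and repeat, draws that many records without
    replacement (seeded per (size, repeat) via SeedSequence spawning),
    decomposes the resulting matrix and records ``min_modes`` at
    ``eta_target``. Returns a tidy frame with columns
    ``subset_size, repeat, k_min``.
    """
    n = len(dataset)
    if n_repeats < 1:
        raise ConfigError("n_repeats must be >= 1")
    for s in subset_sizes:
        if s > n or s < 1:
            raise ConfigError(f"subset size {s} outside [1, {n}]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subset_sizes) * n_repeats)
    rows = []
    ci = 0
    for size in subset_sizes:
        for rep in range(n_repeats):
            rng = np.random.default_rng(children[ci])
            ci += 1
            idx = rng.choice(n, size=size, replace=False)
            sub = dataio.KinematicDataset(
                records=[dataset.records[i] for i in sorted(idx)],
                provenance=dataset.provenance,
                units=dataset.units,
            )
            basis = decompose(assemble_data_matrix(sub, qoi, direction))
            rows.append(
                {
                    "subset_size": size,
                    "repeat": rep,
                    "k_min": min_modes(basis, eta_target),
                }
            )
    return pd.DataFrame(rows)


def build_pca_dataset(
    dataset: dataio.KinematicDataset, eta_target: float = 0.90
) -> tuple[dataio.KinematicDataset, dict]:
    """Low-rank approximation of a whole data set, per QoI/direction.

    Each quantity of interest — linear acceleration, angular velocity and
    angular acceleration, per anatomical direction — is reduced as its own
    data matrix, truncated at the smallest ``k`` reaching ``eta_target``.
    The reconstructed angular acceleration is stored as an explicit channel
    on the output records (downstream rotational metrics then consume the
    reduced acceleration directly rather than re-differentiating the
    reduced velocity). Returns the approximated data set and a dict of the
    per-channel mode counts.
    """
    m = dataset.n_samples
    n = len(dataset)
    lin = np.empty((3, m, n))
    ang = np.empty((3, m, n))
    aac = np.empty((3, m, n))
    kused: dict[str, int] = {}
    for d in range(3):
        for qoi, out, names in (
            ("lin_acc", lin, dataio.LINEAR_DIRECTIONS),
            ("ang_vel", ang, dataio.ANGULAR_DIRECTIONS),
            ("ang_acc", aac, dataio.ANGULAR_DIRECTIONS),
        ):
            basis = decompose(assemble_data_matrix(dataset, qoi, d))
            k = min_modes(basis, eta_target)
            out[d] = reconstruct(basis, k).values
            kused[f"{qoi}_{names[d]}"] = k
    records = []
    for j, rec in enumerate(dataset):
        records.append(
            dataio.KinematicRecord(
                record_id=rec.record_id,
                time=rec.time.copy(),
                lin_acc=lin[:, :, j],
                ang_vel=ang[:, :, j],
                sample_rate=rec.sample_rate,
                ang_acc=aac[:, :, j],
            )
        )
    approx = dataio.KinematicDataset(
        records=records,
        provenance=f"pca eta>={eta_target} of [{dataset.provenance}]",
        units=dict(dataset.units),
    )
    return approx, kused
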