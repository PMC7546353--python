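"""Kinematic data containers, file I/O, and derived kinematic quantities.

A head impact is recorded as 100 ms of 6-DoF kinematics sampled at 1 kHz:
triaxial linear acceleration (m/s²) and triaxial angular velocity (rad/s).
Direction indexing is fixed package-wide:

* angular channels (``ang_vel``/``ang_acc``): 0 = coronal, 1 = sagittal,
  2 = axial;
* linear channels (``lin_acc``): 0 = anterior–posterior,
  1 = inferior–superior, 2 = lateral.

On disk a data set is a directory of one CSV file per impact (header
``t,ax,ay,az,wx,wy,wz``, SI units) plus a JSON ``manifest.json`` naming the
files, the sample rate and the provenance string. The round trip
``read_dataset(write_dataset(ds))`` is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import DatasetValidationError, FormatError

__all__ = [
    "ANGULAR_DIRECTIONS",
    "LINEAR_DIRECTIONS",
    "KinematicRecord",
    "KinematicDataset",
    "read_dataset",
    "write_dataset",
    "derive_angular_acceleration",
    "resultant",
]

ANGULAR_DIRECTIONS = ("coronal", "sagittal", "axial")
LINEAR_DIRECTIONS = ("anterior-posterior", "inferior-superior", "lateral")

_CSV_HEADER = "t,ax,ay,az,wx,wy,wz"
# extended variant for data sets carrying an explicit angular-acceleration
# channel (gx,gy,gz in rad/s^2)
_CSV_HEADER_EXT = _CSV_HEADER + ",gx,gy,gz"
_MANIFEST_NAME = "manifest.json"


@dataclass
class KinematicRecord:
    """One impact: a uniform time base plus six kinematic channels.

    Parameters
    ----------
    record_id
        Unique identifier within a data set.
    time
        Sample times in seconds, uniformly spaced at ``1/sample_rate``.
    lin_acc
        ``(3, m)`` linear acceleration in m/s² (AP, IS, lateral rows).
    ang_vel
        ``(3, m)`` angular velocity in rad/s (coronal, sagittal, axial rows).
    sample_rate
        Sampling frequency in Hz.
    """

    record_id: str
    time: np.ndarray
    lin_acc: np.ndarray
    ang_vel: np.ndarray
    sample_rate: float
    ang_acc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lin_acc = np.atleast_2d(np.asarray(self.lin_acc, dtype=float))
        self.ang_vel = np.atleast_2d(np.asarray(self.ang_vel, dtype=float))
        m = self.time.shape[0]
        if self.lin_acc.shape != (3, m) or self.ang_vel.shape != (3, m):
            raise DatasetValidationError(
                f"record {self.record_id!r}: channel shapes "
                f"{self.lin_acc.shape}/{self.ang_vel.shape} do not match "
                f"(3, {m})"
            )
        if self.ang_acc is not None:
            self.ang_acc = np.atleast_2d(np.asarray(self.ang_acc, dtype=float))
            if self.ang_acc.shape != (3, m):
                raise DatasetValidationError(
                    f"record {self.record_id!r}: ang_acc shape "
                    f"{self.ang_acc.shape} does not match (3, {m})"
                )
        if m >= 2:
            dt = np.diff(self.time)
            if dt.min() <= 0 or not np.allclose(
                dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9
            ):
                raise DatasetValidationError(
                    f"record {self.record_id!r}: time base is not a uniform "
                    f"grid at {self.sample_rate} Hz"
                )
        if not (
            np.all(np.isfinite(self.lin_acc))
            and np.all(np.isfinite(self.ang_vel))
            and (self.ang_acc is None or np.all(np.isfinite(self.ang_acc)))
        ):
            raise DatasetValidationError(
                f"record {self.record_id!r}: non-finite samples"
            )

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]


@dataclass
class KinematicDataset:
    """Ordered collection of :class:`KinematicRecord` sharing one grid."""

    records: list[KinematicRecord]
    provenance: str = ""
    units: dict = field(
        default_factory=lambda: {"lin_acc": "m/s^2", "ang_vel": "rad/s"}
    )

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate record ids: {dupes}")
        if self.records:
            fs = self.records[0].sample_rate
            m = self.records[0].n_samples
            for r in self.records:
                if r.sample_rate != fs or r.n_samples != m:
                    raise DatasetValidationError(
                        f"record {r.record_id!r} does not share the common "
                        f"grid ({fs} Hz, {m} samples)"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[KinematicRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> KinematicRecord:
        return self.records[i]

    @property
    def sample_rate(self) -> float:
        if not self.records:
            raise DatasetValidationError("empty dataset has no sample rate")
        return self.records[0].sample_rate

    @property
    def n_samples(self) -> int:
        if not self.records:
            raise DatasetValidationError("empty dataset has no sample count")
        return self.records[0].n_samples


def write_dataset(dataset: KinematicDataset, path: str | Path) -> Path:
    """Write ``dataset`` to directory ``path`` (one CSV per record + manifest).

    Returns the directory path. Floats are written with ``repr`` precision so
    the round trip is bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in dataset.records:
        fname = f"{rec.record_id}.csv"
        parts = [rec.time, rec.lin_acc.T, rec.ang_vel.T]
        header = _CSV_HEADER
        if rec.ang_acc is not None:
            parts.append(rec.ang_acc.T)
            header = _CSV_HEADER_EXT
        cols = np.column_stack(parts)
        with open(path / fname, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            for row in cols:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
        entries.append({"record_id": rec.record_id, "file": fname})
    manifest = {
        "format": "impactkin-dataset-v1",
        "sample_rate": dataset.sample_rate if dataset.records else None,
        "provenance": dataset.provenance,
        "units": dataset.units,
        "records": entries,
    }
    with open(path / _MANIFEST_NAME, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_dataset(path: str | Path) -> KinematicDataset:
    """Read a data set written by :func:`write_dataset`."""
    path = Path(path)
    mpath = path / _MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no {_MANIFEST_NAME} in {path}")
    with open(mpath, encoding="utf-8") as fh:
        manifest = json.load(fh)
    fs = manifest.get("sample_rate")
    if fs is None:
        raise FormatError(f"{mpath}: manifest missing sample_rate")
    records = []
    for entry in manifest.get("records", []):
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"trace file {fpath} listed in manifest")
        with open(fpath, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header not in (_CSV_HEADER, _CSV_HEADER_EXT):
                raise FormatError(
                    f"{fpath}: expected header {_CSV_HEADER!r} or "
                    f"{_CSV_HEADER_EXT!r}, got {header!r}"
                )
            ncol = 7 if header == _CSV_HEADER else 10
            try:
                data = np.loadtxt(fh, delimiter=",", ndmin=2)
            except ValueError as exc:
                raise FormatError(f"{fpath}: unparseable rows ({exc})") from exc
        if data.shape[1] != ncol:
            raise FormatError(
                f"{fpath}: expected {ncol} columns ({header}), "
                f"got {data.shape[1]}"
            )
        records.append(
            KinematicRecord(
                record_id=entry["record_id"],
                time=data[:, 0],
                lin_acc=data[:, 1:4].T,
                ang_vel=data[:, 4:7].T,
                sample_rate=float(fs),
                ang_acc=data[:, 7:10].T if ncol == 10 else None,
            )
        )
    return KinematicDataset(
        records=records,
        provenance=manifest.get("provenance", ""),
        units=manifest.get("units", {}),
    )


def derive_angular_acceleration(record: KinematicRecord) -> np.ndarray:
    """Angular acceleration (rad/s²) of a record.

    If the record carries an explicit ``ang_acc`` channel (approximation
    data sets reduce angular acceleration as its own quantity of interest),
    that channel is returned. Otherwise it is derived by first-order
    forward differences, ``alpha[d, i] = (omega[d, i+1] - omega[d, i]) *
    sample_rate`` for ``i = 0..m-2``, with the final value replicated so
    the output keeps the input length and all quantities of interest share
    the same data-matrix dimensions.
    """
    if record.ang_acc is not None:
        return record.ang_acc.copy()
    if record.n_samples < 2:
        raise DatasetValidationError(
            "need at least 2 samples to differentiate"
        )
    alpha = np.diff(record.ang_vel, axis=1) * record.sample_rate
    return np.concatenate([alpha, alpha[:, -1:]], axis=1)


def resultant(traces: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of three equal-length component traces."""
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 3:
        raise DatasetValidationError(
            f"expected three equal-length traces, got shape {arr.shape}"
        )
    return np.sqrt(np.sum(arr * arr, axis=0))
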