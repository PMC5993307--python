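"""Reading/writing delimited voxel time series, preprocessing, run config."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal

from .geometry import GeometryConfig


def _read_matrix(path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else ("\t" if "\t" in first else None)
    try:
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: not a rectangular numeric matrix: {exc}") from exc
    return mat


def read_timeseries(path_dD, path_dO, max_nonfinite_fraction: float = 0.0):
    """Read a (dD, dO) pair of voxel x time delimited matrices.

    Rows are voxels, columns are time frames; the two files must agree in
    shape.  Non-finite entries beyond ``max_nonfinite_fraction`` are
    rejected.
    """
    dD = _read_matrix(path_dD)
    dO = _read_matrix(path_dO)
    if dD.shape != dO.shape:
        raise ValueError(f"shape mismatch: {path_dD} is {dD.shape} but "
                         f"{path_dO} is {dO.shape}")
    for name, mat in (("dD", dD), ("dO", dO)):
        bad = np.mean(~np.isfinite(mat))
        if bad > max_nonfinite_fraction:
            raise ValueError(f"{name}: {bad:.1%} non-finite entries exceed the "
                             f"allowed fraction {max_nonfinite_fraction:.1%}")
    return dD, dO


def write_timeseries(path, matrix) -> None:
    np.savetxt(path, np.atleast_2d(matrix), delimiter=",", fmt="%.10e")


def linear_detrend(matrix) -> np.ndarray:
    """Remove each voxel's least-squares line across time.

    Leaves per-voxel zero mean and zero linear trend; idempotent.  Applied
    to the measured dD/dO series before state assignment so that sample
    values are deviations from the (drift-corrected) temporal mean.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] < 2:
        raise ValueError("detrending requires at least 2 frames")
    return signal.detrend(matrix, axis=1, type="linear")


@dataclass
class RunConfig:
    """Centralized run parameters with the field's customary defaults.

    85 % mean saturation, 1.8 Hz sampling, 60-frame maximum stored lag and
    linear detrending mirror a typical continuous-wave breast tomography
    acquisition.
    """

    s0_percent: float = 85.0
    t0_molar: float = 1e-4
    saturation_mode: str = "linearized"
    sampling_rate_hz: float = 1.8
    max_lag: int = 60
    detrend: bool = True
    seed: int = 0

    @property
    def geometry(self) -> GeometryConfig:
        return GeometryConfig(s0_percent=self.s0_percent, t0_molar=self.t0_molar,
                              saturation_mode=self.saturation_mode)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (JSON is a YAML subset and is accepted as-is)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
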