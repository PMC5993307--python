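"""Ten-sector state geometry of the co-varying hemoglobin signal.

The instantaneous hemoglobin signal at a voxel is summarized by five
co-varying components: the two measured concentration deviations from the
temporal mean, ``dO`` (oxyHb) and ``dD`` (deoxyHb), and three dependent
quantities -- total hemoglobin ``dT = dD + dO``, tissue-oxygen exchange
``dE = dD - dO``, and oxygen-saturation deviation ``dS``.  Five straight
lines through the origin of the (dD, dO) plane (the zero sets of the five
components) partition it into ten sectors; each sector is a unique
realizable permutation of the five algebraic signs and defines one "Hb
state".  States are labeled 1..10; the origin, where the direction is
undefined, maps to the sentinel 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNDEFINED = 0
N_STATES = 10

#: component order used throughout: oxy, deoxy, total, exchange, saturation
COMPONENTS = ("O", "D", "T", "E", "S")


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of the state sectors.

    Parameters
    ----------
    s0_percent : float
        Temporal-mean hemoglobin oxygen saturation S0, percent, in (0, 100).
        Sets the inclination of the saturation demarcation line.
    t0_molar : float
        Baseline total hemoglobin concentration T0 (mol/L, > 0).  Only the
        *amplitude* of dS depends on it; state assignment does not.
    saturation_mode : str
        ``"linearized"`` (default): dS = (100/T0)*(dO - (S0/100)*dT), the
        first-order form whose zero set is the straight demarcation line.
        ``"exact"``: dS = 100*(O0+dO)/(T0+dT) - S0.
    """

    s0_percent: float = 85.0
    t0_molar: float = 1e-4
    saturation_mode: str = "linearized"

    def __post_init__(self) -> None:
        if not 0.0 < self.s0_percent < 100.0:
            raise ValueError(f"S0 must lie in (0, 100), got {self.s0_percent}")
        if not self.t0_molar > 0.0:
            raise ValueError(f"T0 must be positive, got {self.t0_molar}")
        if self.saturation_mode not in ("linearized", "exact"):
            raise ValueError(f"unknown saturation_mode {self.saturation_mode!r}")

    @property
    def o0_molar(self) -> float:
        """Baseline oxyHb concentration O0 = T0*S0/100."""
        return self.t0_molar * self.s0_percent / 100.0

    @property
    def d0_molar(self) -> float:
        """Baseline deoxyHb concentration D0 = T0 - O0."""
        return self.t0_molar - self.o0_molar


@dataclass
class HbComponents:
    """The five co-varying signal components (arrays or scalars).

    Concentrations in mol/L; ``dS`` in percent saturation.
    """

    dO: np.ndarray
    dD: np.ndarray
    dT: np.ndarray
    dE: np.ndarray
    dS: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"O": self.dO, "D": self.dD, "T": self.dT, "E": self.dE, "S": self.dS}


@dataclass
class StateSequence:
    """Voxel x time array of state labels in {0, 1, .., 10}."""

    labels: np.ndarray
    sampling_rate: float = 1.8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D voxel x time array")
        lab = self.labels
        if lab.size and (lab.min() < 0 or lab.max() > N_STATES):
            raise ValueError("state labels must lie in {0..10}")

    @property
    def n_voxels(self) -> int:
        return self.labels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[1]


def dependent_components(dD, dO, geometry: GeometryConfig) -> HbComponents:
    """Compute all five Hb components from the two measured ones.

    dT = dD + dO and dE = dD - dO hold exactly.  dS uses the geometry's
    saturation mode; in exact mode a non-positive instantaneous total
    (T0 + dT <= 0) is an invalid baseline and raises ``ValueError``.
    """
    dD = np.asarray(dD, dtype=float)
    dO = np.asarray(dO, dtype=float)
    if not (np.all(np.isfinite(dD)) and np.all(np.isfinite(dO))):
        raise ValueError("non-finite input to dependent_components")
    dT = dD + dO
    dE = dD - dO
    s0, t0 = geometry.s0_percent, geometry.t0_molar
    if geometry.saturation_mode == "exact":
        total = t0 + dT
        if np.any(total <= 0):
            raise ValueError("invalid baseline: T0 + dT <= 0 in exact saturation mode")
        dS = 100.0 * (geometry.o0_molar + dO) / total - s0
    else:
        dS = (100.0 / t0) * (dO - (s0 / 100.0) * dT)
    return HbComponents(dO=dO, dD=dD, dT=dT, dE=dE, dS=dS)


def demarcation_angle(s0_percent: float) -> float:
    """Inclination (degrees from the deoxyHb axis) of the dS = 0 line.

    Equals arctan(S0 / (100 - S0)); 45 degrees at S0 = 50, approaching 90
    as S0 -> 100.
    """
    if not 0.0 < s0_percent < 100.0:
        raise ValueError(f"S0 must lie in (0, 100), got {s0_percent}")
    return float(np.degrees(np.arctan2(s0_percent, 100.0 - s0_percent)))


def _boundary_angles(geometry: GeometryConfig) -> np.ndarray:
    """The ten sector-boundary ray angles in degrees, sorted, in [0, 360)."""
    a = demarcation_angle(geometry.s0_percent)
    half = np.array([0.0, 45.0, a, 90.0, 135.0])
    return np.sort(np.concatenate([half, half + 180.0]))


# states of the sectors [b_k, b_{k+1}) for boundaries sorted from 0 deg:
# [0,45)=6, [45,A)=7, [A,90)=8, [90,135)=9, [135,180)=10, then antipodes 1..5
_SECTOR_STATES = np.array([6, 7, 8, 9, 10, 1, 2, 3, 4, 5])


def assign_state(dD, dO, geometry: GeometryConfig):
    """Assign Hb state labels 1..10 to (dD, dO) samples; (0,0) maps to 0.

    Membership is by the polar angle theta = atan2(dO, dD) binned into
    half-open arcs [lower, upper) anchored at the five boundary lines, so a
    sample lying exactly on a line belongs to the sector counter-clockwise
    of it.  Accepts scalars or arrays (broadcast together).
    """
    dD = np.asarray(dD, dtype=float)
    dO = np.asarray(dO, dtype=float)
    if not (np.all(np.isfinite(dD)) and np.all(np.isfinite(dO))):
        raise ValueError("non-finite input to assign_state")
    theta = np.degrees(np.arctan2(dO, dD)) % 360.0
    bounds = _boundary_angles(geometry)
    idx = np.searchsorted(bounds, theta, side="right") - 1
    labels = _SECTOR_STATES[idx]
    labels = np.where((dD == 0.0) & (dO == 0.0), UNDEFINED, labels)
    if labels.ndim == 0:
        return int(labels)
    return labels.astype(np.int8)


def assign_state_series(dD_matrix, dO_matrix, geometry: GeometryConfig,
                        sampling_rate: float = 1.8) -> StateSequence:
    """Element-wise state assignment of a voxel x time series pair."""
    dD_matrix = np.atleast_2d(np.asarray(dD_matrix, dtype=float))
    dO_matrix = np.atleast_2d(np.asarray(dO_matrix, dtype=float))
    if dD_matrix.shape != dO_matrix.shape:
        raise ValueError(
            f"shape mismatch: dD {dD_matrix.shape} vs dO {dO_matrix.shape}")
    labels = assign_state(dD_matrix, dO_matrix, geometry)
    return StateSequence(labels=np.asarray(labels), sampling_rate=sampling_rate)


def state_sign_table(geometry: GeometryConfig) -> np.ndarray:
    """Canonical 10 x 5 sign pattern of the states, component order (O,D,T,E,S).

    Row ``j`` (0-based) is the sign pattern of state ``j+1`` as +1/-1
    entries, obtained by classifying one interior direction of each sector.
    """
    bounds = _boundary_angles(geometry)
    arcs = np.append(bounds, 360.0)
    table = np.zeros((N_STATES, 5), dtype=int)
    for k in range(N_STATES):
        mid = np.radians((arcs[k] + arcs[k + 1]) / 2.0)
        dD, dO = np.cos(mid), np.sin(mid)
        c = dependent_components(dD, dO, geometry)
        state = _SECTOR_STATES[k]
        table[state - 1] = np.sign(
            [c.dO, c.dD, c.dT, c.dE, c.dS]).astype(int)
    return table


def enumerate_realizable_states(geometry: GeometryConfig,
                                angular_resolution: float = 0.005):
    """Brute-force sweep of directions; returns (count, set of sign patterns).

    Sweeps polar directions 0..360 degrees at the given resolution
    (degrees), computes the 5-component sign pattern at each non-boundary
    direction, and collects the distinct realizable patterns.  With any
    S0 in (0, 100) exactly 10 of the 32 conceivable patterns occur.
    """
    thetas = np.arange(0.0, 360.0, angular_resolution)
    dD = np.cos(np.radians(thetas))
    dO = np.sin(np.radians(thetas))
    c = dependent_components(dD, dO, geometry)
    signs = np.sign(np.stack([c.dO, c.dD, c.dT, c.dE, c.dS], axis=1)).astype(int)
    interior = np.all(signs != 0, axis=1)  # skip directions on a boundary line
    patterns = {tuple(row) for row in signs[interior]}
    return len(patterns), patterns
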