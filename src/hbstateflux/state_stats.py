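"""State-occupancy statistics, first-order model checks, and map similarity.

Includes the observed and model-predicted state volume fractions (the
first-order kinetic relation V_j proportional to sum_f P_fj * tau_fj),
per-state mean amplitudes and their exchange-to-volume ratios, the nRMSD
and Pearson-correlation map-dissimilarity indices, the three-pairing
t-score contrast, and the mass-action regression of intrinsic flux on the
post-minus-pre amplitude difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import GeometryConfig, N_STATES, StateSequence, dependent_components
from .transitions import CoefficientMap


@dataclass
class VolumeFractions:
    """Percent of defined voxel-time samples occupied by each state."""

    v: np.ndarray  # 10-vector, percent
    normalization: float = 1.0  # K of the model-predicted form, else 1

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (N_STATES,):
            raise ValueError("volume fractions must be a 10-vector")


@dataclass
class StateMeanAmplitudes:
    """Per-state mean (dD, dO) points and their dependent projections."""

    mean_dD: np.ndarray
    mean_dO: np.ndarray
    mean_dT: np.ndarray
    mean_dE: np.ndarray
    mean_dS: np.ndarray
    counts: np.ndarray


def volume_fractions(states: StateSequence) -> VolumeFractions:
    """Observed occupancy: V_j = 100 * (samples in state j) / (defined samples)."""
    lab = states.labels
    defined = lab[lab > 0]
    if defined.size == 0:
        raise ValueError("no defined samples: all labels are the undefined sentinel")
    counts = np.bincount(defined.ravel(), minlength=N_STATES + 1)[1:]
    return VolumeFractions(v=100.0 * counts / defined.size)


def predicted_volume_fractions(P: CoefficientMap,
                               tau: CoefficientMap) -> VolumeFractions:
    """First-order model prediction V_j = K * sum_f P_fj * tau_fj.

    Equivalent to the matrix form ``K * diag(P^T Tau)``.  Occupancy of a
    state is proportional to how often it is departed from times the mean
    dwell spent before departing -- the hallmark of first-order kinetics.
    Cells where either factor is undefined contribute zero.
    """
    prod = P.values * tau.values
    prod = np.where(np.isnan(prod), 0.0, prod)
    raw = prod.sum(axis=0)  # sum over final states f, for each initial j
    total = raw.sum()
    if total == 0:
        raise ValueError("empty maps: no defined P*tau products")
    K = 100.0 / total
    return VolumeFractions(v=K * raw, normalization=K)


def model_discrepancy(v_obs: VolumeFractions, v_pred: VolumeFractions) -> float:
    """Mean relative percent discrepancy 100*(V_obs - V_pred)/V_obs over states.

    States with zero observed occupancy are excluded (with a warning).
    """
    obs, pred = v_obs.v, v_pred.v
    ok = obs != 0
    if not ok.all():
        warnings.warn("excluding states with zero observed volume fraction",
                      stacklevel=2)
    if not ok.any():
        raise ValueError("no states with nonzero observed occupancy")
    return float(np.mean(100.0 * (obs[ok] - pred[ok]) / obs[ok]))


def state_mean_amplitudes(dD_matrix, dO_matrix, states: StateSequence,
                          geometry: GeometryConfig) -> StateMeanAmplitudes:
    """Per-state mean (dD, dO) over all samples in the state, plus projections.

    The dependent projections are evaluated at the mean point; by linearity
    of dT, dE and the linearized dS they equal the means of the per-sample
    projections.  Empty states carry NaN means.
    """
    dD_matrix = np.asarray(dD_matrix, dtype=float)
    dO_matrix = np.asarray(dO_matrix, dtype=float)
    if dD_matrix.shape != states.labels.shape or dO_matrix.shape != states.labels.shape:
        raise ValueError("amplitude matrices must match the label array shape")
    lab = states.labels.ravel()
    dD, dO = dD_matrix.ravel(), dO_matrix.ravel()
    counts = np.bincount(lab, minlength=N_STATES + 1)[1:]
    sum_d = np.bincount(lab, weights=dD, minlength=N_STATES + 1)[1:]
    sum_o = np.bincount(lab, weights=dO, minlength=N_STATES + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        mD = np.where(counts > 0, sum_d / np.maximum(counts, 1), np.nan)
        mO = np.where(counts > 0, sum_o / np.maximum(counts, 1), np.nan)
    lin = GeometryConfig(geometry.s0_percent, geometry.t0_molar, "linearized")
    comp = dependent_components(np.nan_to_num(mD), np.nan_to_num(mO), lin)
    empty = counts == 0
    return StateMeanAmplitudes(
        mean_dD=mD, mean_dO=mO,
        mean_dT=np.where(empty, np.nan, comp.dT),
        mean_dE=np.where(empty, np.nan, comp.dE),
        mean_dS=np.where(empty, np.nan, comp.dS),
        counts=counts,
    )


def exchange_to_volume_ratio(means: StateMeanAmplitudes) -> np.ndarray:
    """Dimensionless dE/dT ratio of each state's mean point (NaN where dT = 0)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = means.mean_dE / means.mean_dT
    return np.where(means.mean_dT == 0, np.nan, ratio)


def _common_offdiag(mapA: CoefficientMap, mapB: CoefficientMap):
    a, b = mapA.offdiag, mapB.offdiag
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("no common defined off-diagonal cells")
    return a[ok], b[ok]


def nrmsd(mapA: CoefficientMap, mapB: CoefficientMap) -> float:
    """Normalized root-mean-squared difference over the off-diagonal cells.

    sqrt( sum (a-b)^2 / [(sum a^2 + sum b^2)/2] ): 0 iff the maps agree,
    2 when b = -a, symmetric and invariant to a common rescaling.
    """
    a, b = _common_offdiag(mapA, mapB)
    denom = (np.sum(a ** 2) + np.sum(b ** 2)) / 2.0
    if denom == 0:
        raise ValueError("both maps are identically zero")
    return float(np.sqrt(np.sum((a - b) ** 2) / denom))


def map_correlation(mapA: CoefficientMap, mapB: CoefficientMap) -> float:
    """Pearson correlation of the two maps' common off-diagonal cells."""
    a, b = _common_offdiag(mapA, mapB)
    if a.size < 3:
        raise ValueError("need at least 3 common defined cells")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a map's off-diagonal values")
    return float(np.corrcoef(a, b)[0, 1])


def tscore_index(value_tu: float, control_values) -> float:
    """t-score of the tumor/unaffected pairing against the control pairings.

    ``(x - y) / z`` with y, z the mean and (n-1)-denominator SD of the
    control-pairing values (canonically the three pairings of unaffected
    breasts: L-R, L-U, R-U).
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 control pairings")
    z = controls.std(ddof=1)
    if z == 0:
        raise ValueError("zero spread among control pairings")
    return float((value_tu - controls.mean()) / z)


def mass_action_regression(phi: CoefficientMap, pre_amp: CoefficientMap,
                           post_amp: CoefficientMap):
    """OLS fit of intrinsic flux on the post-minus-pre amplitude difference.

    Returns ``(slope, intercept, r)``.  A mass-action-like first-order
    dependence shows as a strong linear relation; the three inputs may come
    from different averaging pipelines (e.g. group-mean maps), in which
    case the within-accumulator identity phi = post - pre no longer pins
    the slope to 1.
    """
    x = post_amp.values - pre_amp.values
    y = phi.values
    mask = ~(np.isnan(x) | np.isnan(y))
    np.fill_diagonal(mask, False)
    xs, ys = x[mask], y[mask]
    if xs.size < 3:
        raise ValueError("need at least 3 defined cells for regression")
    if np.std(xs) == 0:
        raise ValueError("degenerate predictor: post-pre difference is constant")
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
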