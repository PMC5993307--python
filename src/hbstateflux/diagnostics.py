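"""Bilateral (left/right) diagnostic metrics over cohorts of coefficient maps.

Each subject contributes one coefficient map per breast for every quantity
of interest.  The laterality-corrected relative inter-breast difference
(the Z metric) is the input to per-cell group comparisons: pooled-variance
Student t-tests of the cancer vs. non-cancer inter-breast differences, and
rank-based ROC/AUC maps of diagnostic accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import N_STATES
from .transitions import CoefficientMap

GROUPS = ("cancer", "non_cancer")
LATERALITIES = ("left", "right", "none")


@dataclass
class Subject:
    """One subject's bilateral coefficient maps.

    ``maps_left`` / ``maps_right`` are keyed by a quantity name such as
    ``"k"``, ``"P"``, ``"phi_S"`` or ``"k_phi_S"``.
    """

    subject_id: str
    group: str
    laterality: str = "none"
    maps_left: dict[str, CoefficientMap] = field(default_factory=dict)
    maps_right: dict[str, CoefficientMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        if self.group == "cancer" and self.laterality == "none":
            raise ValueError("cancer subjects must have a tumor laterality")
        if self.group == "non_cancer" and self.laterality != "none":
            raise ValueError("non-cancer subjects must have laterality 'none'")

    @property
    def tumor_maps(self) -> dict[str, CoefficientMap]:
        return self.maps_left if self.laterality == "left" else self.maps_right

    @property
    def unaffected_maps(self) -> dict[str, CoefficientMap]:
        return self.maps_right if self.laterality == "left" else self.maps_left


@dataclass
class Cohort:
    subjects: list[Subject]

    def group(self, name: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == name]

    @property
    def cancer(self) -> list[Subject]:
        return self.group("cancer")

    @property
    def non_cancer(self) -> list[Subject]:
        return self.group("non_cancer")


def _nanmean_stack(values: list[np.ndarray]) -> np.ndarray:
    stack = np.stack(values)
    valid = ~np.isnan(stack)
    cnt = valid.sum(axis=0)
    tot = np.where(valid, stack, 0.0).sum(axis=0)
    return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


def nc_reference_means(cohort: Cohort, key: str):
    """Cell-wise non-cancer group means of the left and right maps."""
    nc = cohort.non_cancer
    if not nc:
        raise ValueError("cohort has no non-cancer subjects")
    left = _nanmean_stack([s.maps_left[key].values for s in nc])
    right = _nanmean_stack([s.maps_right[key].values for s in nc])
    return left, right


def z_metric(cohort: Cohort, key: str,
             nc_means=None) -> dict[str, CoefficientMap]:
    """Laterality-corrected relative percent inter-breast difference.

    For left-tumor and non-cancer subjects ``Z = 100*(Y_l - Y_r)/Y_r``.
    For right-tumor subjects the raw values are first corrected with the
    non-cancer reference means so that the tumor-bearing side plays the
    same role as a left tumor:
    ``Z = 100*([Y_r - nc_r + nc_l] - [Y_l - nc_l + nc_r]) /
    (Y_l - nc_l + nc_r)``.
    Zero denominators produce NaN cells.  Returns a map per subject id.
    """
    if nc_means is None:
        nc_means = nc_reference_means(cohort, key)
    nc_l, nc_r = nc_means
    out: dict[str, CoefficientMap] = {}
    for s in cohort.subjects:
        yl = s.maps_left[key].values
        yr = s.maps_right[key].values
        if s.laterality == "right":
            num = (yr - nc_r + nc_l) - (yl - nc_l + nc_r)
            den = yl - nc_l + nc_r
        else:
            num = yl - yr
            den = yr
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(den != 0, 100.0 * num / np.where(den != 0, den, 1.0),
                         np.nan)
        out[s.subject_id] = CoefficientMap(z, kind="Z", component=None, units="%")
    return out


def _interbreast_differences(cohort: Cohort, key: str):
    """Per-subject T-U differences (cancer) and L-R differences (non-cancer)."""
    cancer = [s.tumor_maps[key].values - s.unaffected_maps[key].values
              for s in cohort.cancer]
    control = [s.maps_left[key].values - s.maps_right[key].values
               for s in cohort.non_cancer]
    return cancer, control


def group_difference_ttests(cohort: Cohort, key: str) -> CoefficientMap:
    """Cell-wise two-sample Student (pooled-variance) t-tests of inter-breast
    differences, cancer (tumor minus unaffected) vs. non-cancer (left minus
    right); two-sided p-values.  Cells with fewer than 2 subjects per group
    are NaN."""
    cancer, control = _interbreast_differences(cohort, key)
    if not cancer or not control:
        raise ValueError("both groups must be non-empty")
    a = np.stack(cancer)
    b = np.stack(control)
    p = np.full((N_STATES, N_STATES), np.nan)
    for f in range(N_STATES):
        for i in range(N_STATES):
            if f == i:
                continue
            x = a[:, f, i]
            y = b[:, f, i]
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            if x.size < 2 or y.size < 2:
                continue
            res = stats.ttest_ind(x, y, equal_var=True)
            p[f, i] = res.pvalue
    return CoefficientMap(p, kind="pvalue", units="")


def auc_percent(positives, negatives) -> float:
    """Rank-sum (Mann-Whitney) AUC with midrank tie handling, in percent.

    Probability (x100) that a randomly drawn positive-class value exceeds a
    randomly drawn negative-class value, ties counting one half.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(100.0 * u / (pos.size * neg.size))


def roc_auc_map(z_cancer: list[CoefficientMap],
                z_noncancer: list[CoefficientMap],
                fold: bool = False) -> CoefficientMap:
    """Cell-wise AUC (percent) of the cancer vs. non-cancer Z distributions.

    The cancer group is the positive class; the stored values are the raw
    oriented AUC.  ``fold=True`` returns max(AUC, 100-AUC) instead, for
    reports where only discriminability matters.  NaN cells are excluded
    listwise per cell; cells left with an empty group are NaN.
    """
    if not z_cancer or not z_noncancer:
        raise ValueError("both groups must be non-empty")
    a = np.stack([m.values for m in z_cancer])
    b = np.stack([m.values for m in z_noncancer])
    auc = np.full((N_STATES, N_STATES), np.nan)
    for f in range(N_STATES):
        for i in range(N_STATES):
            if f == i:
                continue
            x = a[:, f, i]
            y = b[:, f, i]
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            if x.size == 0 or y.size == 0:
                continue
            val = auc_percent(x, y)
            auc[f, i] = max(val, 100.0 - val) if fold else val
    return CoefficientMap(auc, kind="AUC", units="%")
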