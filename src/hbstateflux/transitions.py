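"""Variable-dwell-time transition counting and coefficient estimation.

A voxel's label series is scanned for *direct* transitions only: starting
from a pre-transition frame, the first later frame with a different state
defines the transition, its dwell being the number of frames ``n`` between
the two; the post-transition frame then becomes the next pre-transition
frame.  Counts are stored in a 10 x 10 x N accumulator indexed
[final, initial, lag], alongside matching accumulators of the change in
each Hb component across the transition and of the component values at the
pre- and post-transition frames.

From the accumulator the 10 x 10 coefficient maps follow:

* ``P``   -- transition probability, percent of all direct transitions,
             normalized so the 90 off-diagonal cells sum to 100
* ``tau`` -- mean dwell (frames) preceding each transition type
* ``k``   -- rate constant 1/tau (frame^-1, or s^-1 via the sampling rate)
* ``phi`` -- intrinsic flux: mean per-transition change of a component
* ``m``   -- transition mass P*phi, and the rate-weighted products k*phi,
             k*m, plus pre/post mean amplitudes, Ohm-analogy voltages
             k/P and k*phi/P, and pairwise asymmetries Y_fi - Y_if
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import COMPONENTS, N_STATES, StateSequence, state_sign_table

DEFAULT_MAX_LAG = 60

STATE_LABELS = [str(j) for j in range(1, N_STATES + 1)]


@dataclass
class CoefficientMap:
    """A labeled 10 x 10 matrix of one transition coefficient.

    ``values[f-1, i-1]`` refers to transitions from state ``i`` into state
    ``f`` (row = final, column = initial).  The main diagonal and cells with
    no recorded transitions carry NaN.
    """

    values: np.ndarray
    kind: str
    component: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STATES, N_STATES):
            raise ValueError("coefficient map must be 10 x 10")
        np.fill_diagonal(self.values, np.nan)

    @property
    def offdiag(self) -> np.ndarray:
        """The 90 off-diagonal values in row-major order."""
        mask = ~np.eye(N_STATES, dtype=bool)
        return self.values[mask]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(STATE_LABELS, name="to_state"),
                            columns=pd.Index(STATE_LABELS, name="from_state"))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def to_long(self) -> pd.DataFrame:
        """Long-format records (from_state, to_state, kind, component, value)."""
        rows = []
        for f in range(N_STATES):
            for i in range(N_STATES):
                if f == i:
                    continue
                rows.append((i + 1, f + 1, self.kind, self.component or "",
                             self.values[f, i]))
        return pd.DataFrame(rows, columns=["from_state", "to_state", "kind",
                                           "component", "value"])

    @classmethod
    def from_csv(cls, path, kind: str = "", component: str | None = None,
                 units: str = "") -> "CoefficientMap":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), kind=kind,
                   component=component, units=units)


@dataclass
class TransitionAccumulator:
    """Lag-resolved transition counts plus per-component change sums.

    ``a_tc[f-1, i-1, n-1]`` counts direct i -> f transitions with dwell
    ``n`` frames; ``a_x[X][f-1, i-1, n-1]`` sums the component changes
    (Eq-style post minus pre values) over those transitions; ``pre_sum`` /
    ``post_sum`` hold the component values at the first frame of the pre-
    and post-transition intervals, summed per (f, i).
    """

    a_tc: np.ndarray
    a_x: dict[str, np.ndarray]
    pre_sum: dict[str, np.ndarray]
    post_sum: dict[str, np.ndarray]
    sampling_rate: float = 1.8

    @property
    def max_lag(self) -> int:
        return self.a_tc.shape[2]

    @property
    def counts(self) -> np.ndarray:
        """10 x 10 lag-summed transition counts."""
        return self.a_tc.sum(axis=2)

    @property
    def n_transitions(self) -> int:
        return int(self.a_tc.sum())

    def __add__(self, other: "TransitionAccumulator") -> "TransitionAccumulator":
        n = max(self.max_lag, other.max_lag)
        a, b = self._padded(n), other._padded(n)
        return TransitionAccumulator(
            a_tc=a.a_tc + b.a_tc,
            a_x={x: a.a_x[x] + b.a_x[x] for x in a.a_x},
            pre_sum={x: a.pre_sum[x] + b.pre_sum[x] for x in a.pre_sum},
            post_sum={x: a.post_sum[x] + b.post_sum[x] for x in a.post_sum},
            sampling_rate=self.sampling_rate,
        )

    def _padded(self, n: int) -> "TransitionAccumulator":
        if n == self.max_lag:
            return self
        pad = ((0, 0), (0, 0), (0, n - self.max_lag))
        return TransitionAccumulator(
            a_tc=np.pad(self.a_tc, pad),
            a_x={x: np.pad(v, pad) for x, v in self.a_x.items()},
            pre_sum=dict(self.pre_sum), post_sum=dict(self.post_sum),
            sampling_rate=self.sampling_rate,
        )


def _runs(labels: np.ndarray):
    """Run-length encode one voxel's label series -> (run_labels, starts, lengths)."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.append(starts, labels.size))
    return labels[starts], starts, lengths


def accumulate_transitions(states: StateSequence,
                           components: dict[str, np.ndarray] | None = None,
                           max_lag: int = DEFAULT_MAX_LAG) -> TransitionAccumulator:
    """Count all direct state transitions of a voxel x time label array.

    ``components`` maps component names (subset of ``("O","D","T","E","S")``)
    to voxel x time value matrices of the same shape as the labels; their
    transition changes and pre/post amplitudes are accumulated alongside the
    counts.  Runs of the undefined label 0 break the scan: no transition is
    recorded into, out of, or across them.  A run reaching the end of the
    series is never counted.  The lag axis starts at ``max_lag`` layers and
    grows automatically if a longer dwell occurs.
    """
    labels = states.labels
    if labels.shape[1] < 2:
        raise ValueError("transition analysis requires at least 2 frames")
    components = components or {}
    for x, mat in components.items():
        if x not in COMPONENTS:
            raise ValueError(f"unknown component {x!r}")
        if np.shape(mat) != labels.shape:
            raise ValueError(f"component {x!r} shape {np.shape(mat)} does not "
                             f"match labels {labels.shape}")

    # first pass over voxels to learn the longest counted dwell
    per_voxel = []
    longest = 0
    for v in range(labels.shape[0]):
        run_labels, starts, lengths = _runs(labels[v])
        # consecutive run pairs (i -> f) with both labels defined; final run
        # never counted (its successor does not exist)
        ok = (run_labels[:-1] > 0) & (run_labels[1:] > 0)
        j = np.flatnonzero(ok)
        if j.size:
            longest = max(longest, int(lengths[j].max()))
        per_voxel.append((run_labels, starts, lengths, j))

    n_lag = max(max_lag, longest)
    a_tc = np.zeros((N_STATES, N_STATES, n_lag), dtype=np.int64)
    a_x = {x: np.zeros((N_STATES, N_STATES, n_lag)) for x in components}
    pre_sum = {x: np.zeros((N_STATES, N_STATES)) for x in components}
    post_sum = {x: np.zeros((N_STATES, N_STATES)) for x in components}

    for v, (run_labels, starts, lengths, j) in enumerate(per_voxel):
        if not j.size:
            continue
        i_state = run_labels[j] - 1
        f_state = run_labels[j + 1] - 1
        n = lengths[j]  # dwell in the pre-transition state, frames
        pre_t = starts[j]
        post_t = starts[j + 1]
        np.add.at(a_tc, (f_state, i_state, n - 1), 1)
        for x, mat in components.items():
            delta = mat[v, post_t] - mat[v, pre_t]
            np.add.at(a_x[x], (f_state, i_state, n - 1), delta)
            np.add.at(pre_sum[x], (f_state, i_state), mat[v, pre_t])
            np.add.at(post_sum[x], (f_state, i_state), mat[v, post_t])

    return TransitionAccumulator(a_tc=a_tc, a_x=a_x, pre_sum=pre_sum,
                                 post_sum=post_sum,
                                 sampling_rate=states.sampling_rate)


def transition_probability(acc: TransitionAccumulator) -> CoefficientMap:
    """Percent share of each ordered state pair among all direct transitions.

    Normalized over the 90 off-diagonal cells so they sum to exactly 100,
    which makes maps averageable across subjects.
    """
    counts = acc.counts.astype(float)
    total = counts.sum()  # diagonal is structurally zero
    if total == 0:
        raise ValueError("empty accumulator: no transitions recorded")
    return CoefficientMap(100.0 * counts / total, kind="P", units="%")


def mean_lag(acc: TransitionAccumulator) -> CoefficientMap:
    """Mean dwell tau (frames) preceding each transition type; NaN if unseen."""
    n = np.arange(1, acc.max_lag + 1)
    num = (acc.a_tc * n).sum(axis=2).astype(float)
    den = acc.counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return CoefficientMap(tau, kind="tau", units="frames")


def rate_constants(acc: TransitionAccumulator, in_hz: bool = True) -> CoefficientMap:
    """Rate constants k = 1/tau; in s^-1 when ``in_hz`` (default), else frame^-1."""
    tau = mean_lag(acc).values
    with np.errstate(invalid="ignore", divide="ignore"):
        k = 1.0 / tau
    if in_hz:
        k = k * acc.sampling_rate
        units = "1/s"
    else:
        units = "1/frame"
    return CoefficientMap(k, kind="k", units=units)


def intrinsic_flux(acc: TransitionAccumulator, component: str) -> CoefficientMap:
    """Mean per-transition change of one Hb component (Eq-6-style ratio)."""
    if component not in acc.a_x:
        raise ValueError(f"component {component!r} was not accumulated")
    num = acc.a_x[component].sum(axis=2)
    den = acc.counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    units = "%" if component == "S" else "mol/L"
    return CoefficientMap(phi, kind="phi", component=component, units=units)


def transition_mass(P: CoefficientMap, phi: CoefficientMap) -> CoefficientMap:
    """Transition mass m = P * phi: component moved per 100 total transitions."""
    return CoefficientMap(P.values * phi.values, kind="m",
                          component=phi.component, units=phi.units)


def weighted_coefficients(k: CoefficientMap, phi: CoefficientMap,
                          m: CoefficientMap):
    """Rate-weighted products (k*phi, k*m): change per unit time, not per transition."""
    per = "s" if k.units == "1/s" else "frame"
    kphi = CoefficientMap(k.values * phi.values, kind="k_phi",
                          component=phi.component, units=f"{phi.units}/{per}")
    km = CoefficientMap(k.values * m.values, kind="k_m",
                        component=m.component, units=f"{m.units}/{per}")
    return kphi, km


def pre_post_amplitudes(acc: TransitionAccumulator, component: str):
    """Mean component amplitude at the first pre- and post-transition frames.

    The identity ``post_amp - pre_amp == phi`` holds exactly cell-wise,
    because both sides telescope over the same set of transitions.
    """
    if component not in acc.pre_sum:
        raise ValueError(f"component {component!r} was not accumulated")
    den = acc.counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pre = np.where(den > 0, acc.pre_sum[component] / np.where(den > 0, den, 1.0),
                       np.nan)
        post = np.where(den > 0, acc.post_sum[component] / np.where(den > 0, den, 1.0),
                        np.nan)
    units = "%" if component == "S" else "mol/L"
    return (CoefficientMap(pre, kind="pre_amp", component=component, units=units),
            CoefficientMap(post, kind="post_amp", component=component, units=units))


def ohmic_voltages(k: CoefficientMap, P: CoefficientMap,
                   phi: CoefficientMap | None = None) -> CoefficientMap:
    """Ohm-analogy voltage V = k/P (or k*phi/P with a component flux).

    Treating P (or P*phi) as a current and k as a conductance, V is the
    driving "voltage" of each transition edge.  Cells with P = 0 are NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(P.values > 0, k.values / P.values, np.nan)
    if phi is None:
        return CoefficientMap(v, kind="V_TC", units=f"({k.units})/%")
    return CoefficientMap(v * phi.values, kind="V_X", component=phi.component,
                          units=f"{phi.units}.{k.units}/%")


def asymmetry_map(Y: CoefficientMap) -> CoefficientMap:
    """Pairwise asymmetry Y_fi - Y_if; antisymmetric by construction."""
    return CoefficientMap(Y.values - Y.values.T, kind="asymmetry",
                          component=Y.component, units=Y.units)


def forced_sign_regions(geometry, component: str) -> np.ndarray:
    """Cells whose flux sign is forced by the state sign patterns.

    Returns a 10 x 10 matrix with +1 where the component goes from below to
    above its mean (flux must be positive), -1 for the reverse, and 0 where
    both end states share the component's sign (mixed increments possible).
    """
    table = state_sign_table(geometry)
    col = COMPONENTS.index(component)
    s = table[:, col]  # sign of the component in each state, by label-1
    sign_i = s[np.newaxis, :]  # column = initial state
    sign_f = s[:, np.newaxis]  # row = final state
    forced = np.zeros((N_STATES, N_STATES), dtype=int)
    forced[(sign_i < 0) & (sign_f > 0)] = 1
    forced[(sign_i > 0) & (sign_f < 0)] = -1
    np.fill_diagonal(forced, 0)
    return forced


def mean_maps(maps: list[CoefficientMap]) -> CoefficientMap:
    """Unweighted cell-wise mean across subjects' maps, skipping NaN cells."""
    if not maps:
        raise ValueError("no maps to average")
    stack = np.stack([m.values for m in maps])
    valid = ~np.isnan(stack)
    cnt = valid.sum(axis=0)
    tot = np.where(valid, stack, 0.0).sum(axis=0)
    avg = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    first = maps[0]
    return CoefficientMap(avg, kind=first.kind, component=first.component,
                          units=first.units)
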