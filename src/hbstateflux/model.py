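"""Model/Results interface over the finite-state hemoglobin analysis.

``HbStateModel`` holds one breast's measured voxel x time series pair and
the run configuration; ``fit()`` performs detrending, dependent-component
computation, state assignment and transition accumulation, returning an
``HbStateResults`` whose properties expose every coefficient map and
occupancy statistic, a ``summary()`` table, and CSV export.
"""

from __future__ import annotations

from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hbio
from . import state_stats, transitions
from .geometry import (COMPONENTS, GeometryConfig, N_STATES, StateSequence,
                       assign_state_series, dependent_components)
from .transitions import CoefficientMap


class HbStateModel:
    """Finite-state transition model of one breast's hemoglobin time series.

    Parameters
    ----------
    dD, dO : array_like, voxels x frames
        Measured deoxyHb / oxyHb concentration changes (mol/L).
    geometry : GeometryConfig, optional
        State-sector geometry (default: S0 = 85 %).
    sampling_rate : float
        Frames per second (default 1.8 Hz).
    detrend : bool
        Remove each voxel's least-squares linear trend before analysis
        (default True), making samples deviations from the temporal mean.
    """

    def __init__(self, dD, dO, geometry: GeometryConfig | None = None,
                 sampling_rate: float = 1.8, detrend: bool = True):
        dD = np.atleast_2d(np.asarray(dD, dtype=float))
        dO = np.atleast_2d(np.asarray(dO, dtype=float))
        if dD.shape != dO.shape:
            raise ValueError(f"dD {dD.shape} and dO {dO.shape} must agree in shape")
        self.geometry = geometry or GeometryConfig()
        self.sampling_rate = float(sampling_rate)
        self.detrend = bool(detrend)
        if detrend:
            dD = hbio.linear_detrend(dD)
            dO = hbio.linear_detrend(dO)
        self.dD, self.dO = dD, dO

    @classmethod
    def from_files(cls, path_dD, path_dO, config: hbio.RunConfig | None = None
                   ) -> "HbStateModel":
        config = config or hbio.RunConfig()
        dD, dO = hbio.read_timeseries(path_dD, path_dO)
        return cls(dD, dO, geometry=config.geometry,
                   sampling_rate=config.sampling_rate_hz, detrend=config.detrend)

    @property
    def n_voxels(self) -> int:
        return self.dD.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dD.shape[1]

    def fit(self, max_lag: int = transitions.DEFAULT_MAX_LAG,
            rate_in_hz: bool = True) -> "HbStateResults":
        """Assign states and accumulate transitions; returns the results."""
        comp = dependent_components(self.dD, self.dO, self.geometry)
        states = assign_state_series(self.dD, self.dO, self.geometry,
                                     self.sampling_rate)
        acc = transitions.accumulate_transitions(states, comp.as_dict(),
                                                 max_lag=max_lag)
        return HbStateResults(self, states, acc, comp, rate_in_hz=rate_in_hz)


class HbStateResults:
    """Fitted coefficient maps and occupancy statistics of one breast series."""

    def __init__(self, model: HbStateModel, states: StateSequence,
                 accumulator: transitions.TransitionAccumulator, components,
                 rate_in_hz: bool = True):
        self.model = model
        self.states = states
        self.accumulator = accumulator
        self.components = components
        self.rate_in_hz = rate_in_hz

    # -- transition coefficient maps -------------------------------------
    @cached_property
    def P(self) -> CoefficientMap:
        """Transition probabilities, percent (off-diagonal sums to 100)."""
        return transitions.transition_probability(self.accumulator)

    @cached_property
    def tau(self) -> CoefficientMap:
        """Mean dwell preceding each transition type, frames."""
        return transitions.mean_lag(self.accumulator)

    @cached_property
    def k(self) -> CoefficientMap:
        """Rate constants 1/tau (s^-1 by default)."""
        return transitions.rate_constants(self.accumulator, in_hz=self.rate_in_hz)

    def phi(self, component: str) -> CoefficientMap:
        """Intrinsic flux of one Hb component (mean change per transition)."""
        return transitions.intrinsic_flux(self.accumulator, component)

    def mass(self, component: str) -> CoefficientMap:
        """Transition mass m = P * phi."""
        return transitions.transition_mass(self.P, self.phi(component))

    def weighted(self, component: str):
        """Rate-weighted maps (k*phi, k*m)."""
        return transitions.weighted_coefficients(self.k, self.phi(component),
                                                 self.mass(component))

    def pre_post_amplitudes(self, component: str):
        """Mean component amplitude at the pre-/post-transition frames."""
        return transitions.pre_post_amplitudes(self.accumulator, component)

    def voltages(self, component: str | None = None) -> CoefficientMap:
        """Ohm-analogy voltages V = k/P (or k*phi/P)."""
        phi = self.phi(component) if component else None
        return transitions.ohmic_voltages(self.k, self.P, phi)

    def asymmetry(self, which: str = "P",
                  component: str | None = None) -> CoefficientMap:
        """Y_fi - Y_if asymmetry of a named coefficient map."""
        return transitions.asymmetry_map(self.coefficient(which, component))

    def coefficient(self, kind: str,
                    component: str | None = None) -> CoefficientMap:
        """Look up a map by kind: P, tau, k, phi, m, k_phi, k_m, V."""
        if kind in ("P", "tau", "k"):
            return getattr(self, kind)
        if kind == "phi":
            return self.phi(component)
        if kind == "m":
            return self.mass(component)
        if kind in ("k_phi", "k_m"):
            kphi, km = self.weighted(component)
            return kphi if kind == "k_phi" else km
        if kind == "V":
            return self.voltages(component)
        if kind in ("pre_amp", "post_amp"):
            pre, post = self.pre_post_amplitudes(component)
            return pre if kind == "pre_amp" else post
        raise ValueError(f"unknown coefficient kind {kind!r}")

    def named_maps(self, components=("D", "E", "O", "S", "T")) -> dict[str, CoefficientMap]:
        """All standard maps keyed like ``"k"``, ``"phi_S"``, ``"k_m_T"``."""
        out = {"P": self.P, "tau": self.tau, "k": self.k}
        for x in components:
            out[f"phi_{x}"] = self.phi(x)
            out[f"m_{x}"] = self.mass(x)
            kphi, km = self.weighted(x)
            out[f"k_phi_{x}"] = kphi
            out[f"k_m_{x}"] = km
            pre, post = self.pre_post_amplitudes(x)
            out[f"pre_amp_{x}"] = pre
            out[f"post_amp_{x}"] = post
        return out

    # -- occupancy statistics --------------------------------------------
    @cached_property
    def volume_fractions(self) -> state_stats.VolumeFractions:
        """Observed percent occupancy of each state."""
        return state_stats.volume_fractions(self.states)

    @cached_property
    def predicted_volume_fractions(self) -> state_stats.VolumeFractions:
        """First-order model prediction K * diag(P^T tau)."""
        return state_stats.predicted_volume_fractions(self.P, self.tau)

    @cached_property
    def volume_model_discrepancy(self) -> float:
        """Mean relative percent discrepancy of observed vs predicted occupancy."""
        return state_stats.model_discrepancy(self.volume_fractions,
                                             self.predicted_volume_fractions)

    @cached_property
    def state_mean_amplitudes(self) -> state_stats.StateMeanAmplitudes:
        return state_stats.state_mean_amplitudes(self.model.dD, self.model.dO,
                                                 self.states, self.model.geometry)

    @cached_property
    def exchange_to_volume_ratio(self) -> np.ndarray:
        """Per-state dE/dT ratio of the state-mean amplitude point."""
        return state_stats.exchange_to_volume_ratio(self.state_mean_amplitudes)

    # -- reporting --------------------------------------------------------
    @property
    def n_transitions(self) -> int:
        return self.accumulator.n_transitions

    @property
    def n_undefined_samples(self) -> int:
        return int(np.sum(self.states.labels == 0))

    def summary(self) -> str:
        counts = self.accumulator.counts
        missing = int(np.sum(counts == 0)) - N_STATES  # exclude diagonal
        k_vals = self.k.offdiag
        lines = [
            "Hb state-flux model results",
            "=" * 43,
            f"{'voxels':<28}{self.model.n_voxels:>15}",
            f"{'frames':<28}{self.model.n_frames:>15}",
            f"{'sampling rate (Hz)':<28}{self.model.sampling_rate:>15.3f}",
            f"{'detrended':<28}{str(self.model.detrend):>15}",
            f"{'S0 (%)':<28}{self.model.geometry.s0_percent:>15.1f}",
            f"{'undefined samples':<28}{self.n_undefined_samples:>15}",
            f"{'direct transitions':<28}{self.n_transitions:>15}",
            f"{'unseen transition types':<28}{missing:>15}",
            f"{'mean dwell (frames)':<28}{np.nanmean(self.tau.offdiag):>15.3f}",
            (f"{'rate constant range':<28}"
             f"{np.nanmin(k_vals):>7.3f}-{np.nanmax(k_vals):<7.3f}"
             f"{self.k.units:>7}"),
            (f"{'volume-model discrepancy':<28}"
             f"{self.volume_model_discrepancy:>14.3f}%"),
        ]
        vf = self.volume_fractions.v
        lines.append("-" * 43)
        lines.append("state volume fractions (%):")
        for j in range(N_STATES):
            lines.append(f"  state {j + 1:>2}: {vf[j]:6.2f}")
        return "\n".join(lines)

    def save_maps(self, outdir, components=("D", "E", "O", "S", "T")) -> None:
        """Write every named map as a 10x10 CSV plus one long-format CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        long_frames = []
        for name, cmap in self.named_maps(components).items():
            cmap.to_csv(outdir / f"{name}.csv")
            long_frames.append(cmap.to_long())
        pd.concat(long_frames, ignore_index=True).to_csv(
            outdir / "coefficients_long.csv", index=False)

    def plot_map(self, kind: str = "k", component: str | None = None, ax=None):
        """Heatmap of one coefficient map (row = final, column = initial)."""
        import matplotlib.pyplot as plt

        cmap = self.coefficient(kind, component)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(cmap.values, origin="upper",
                       extent=(0.5, 10.5, 10.5, 0.5))
        label = kind if component is None else f"{kind}({component})"
        ax.set_xlabel("initial state")
        ax.set_ylabel("final state")
        ax.set_title(f"{label} [{cmap.units}]" if cmap.units else label)
        ax.figure.colorbar(im, ax=ax)
        return ax
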