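"""Simulated electrophysiology from iteration-resolved belief trajectories.

Each belief unit (one hidden-state factor, one level, one represented time
step) is read out as a firing rate: the policy-averaged posterior
expectation at every update sweep, concatenated across the trial's
observation epochs.  The corresponding local field potential is the rate of
change of the policy-averaged depolarization, summed over a population.
Rasters render rates either as a density image or as a seeded Bernoulli
point process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EngineSettings, frame_posterior
from .environment import TrialRecord
from .model import GenerativeModel

__all__ = ["UnitTrace", "LfpTrace", "firing_rates", "local_field_potentials", "raster", "traces_to_frame"]


@dataclass
class UnitTrace:
    """Firing rate and depolarization of one belief unit across a trial.

    ``rate[b]`` is the Bayesian-model-average expectation (in [0, 1]) that
    the factor occupies ``level`` at represented time ``tau``, at within-
    trial bin ``b`` (epoch-sweep order); ``v`` is the matching
    policy-averaged depolarization.
    """

    factor: str
    level: str
    tau: int  # represented time step, 1-based
    rate: np.ndarray
    v: np.ndarray


@dataclass
class LfpTrace:
    """Signed population LFP: first difference of summed depolarization."""

    factor: str
    lfp: np.ndarray


def firing_rates(
    model: GenerativeModel,
    record: TrialRecord,
    settings: EngineSettings | None = None,
) -> list[UnitTrace]:
    """Policy-averaged belief trajectories for every unit in the trial.

    The weights at each bin are the policy posterior implied by that sweep's
    free energies, so commitment to a choice develops continuously within an
    epoch.  Bins concatenate the epochs' sweeps: ``T * n_iter`` in total.
    """
    if record.beliefs is None or not record.beliefs.trace:
        raise ValueError("firing_rates: trial record carries no iteration trace")
    frames = record.beliefs.trace
    weights = [frame_posterior(fr, settings) for fr in frames]
    n_bins = len(frames)
    traces = []
    for n, f in enumerate(model.factors):
        for tau in range(1, model.T + 1):
            rates = np.empty((n_bins, f.n))
            vs = np.empty((n_bins, f.n))
            for b, fr in enumerate(frames):
                w = weights[b]
                # convex combination; clip float-epsilon overshoot
                rates[b] = np.clip(w @ fr.s[n][:, tau - 1, :], 0.0, 1.0)
                vs[b] = w @ fr.v[n][:, tau - 1, :]
            for lv, label in enumerate(f.levels):
                traces.append(
                    UnitTrace(
                        factor=f.name,
                        level=label,
                        tau=tau,
                        rate=rates[:, lv].copy(),
                        v=vs[:, lv].copy(),
                    )
                )
    return traces


def local_field_potentials(
    model: GenerativeModel, record: TrialRecord, window: int = 1
) -> list[LfpTrace]:
    """Per-factor LFP: first difference of the summed policy-averaged v.

    ``window`` > 1 applies a centered moving average to the differenced
    signal.  The trace is zero wherever beliefs are static.
    """
    if window < 1:
        raise ValueError("local_field_potentials: window must be >= 1")
    units = firing_rates(model, record)
    out = []
    for f in model.factors:
        total_v = np.sum([u.v for u in units if u.factor == f.name], axis=0)
        lfp = np.diff(total_v, prepend=total_v[0])
        if window > 1:
            kernel = np.ones(window) / window
            lfp = np.convolve(lfp, kernel, mode="same")
        out.append(LfpTrace(factor=f.name, lfp=lfp))
    return out


def raster(
    units: list[UnitTrace],
    mode: str = "density",
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Raster matrix (units x bins) from firing rates.

    ``density``: grayscale rate image.  ``point-process``: independent
    Bernoulli events per bin with probability ``min(scale * rate, 1)``.
    """
    rates = np.stack([u.rate for u in units])
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("raster: rates must lie in [0, 1]")
    if mode == "density":
        return rates
    if mode == "point-process":
        if rng is None:
            raise ValueError("raster: point-process mode needs an rng")
        return (rng.random(rates.shape) < np.clip(scale * rates, 0, 1)).astype(float)
    raise ValueError(f"raster: unknown mode {mode!r}")


def traces_to_frame(units: list[UnitTrace]) -> pd.DataFrame:
    """Long-format table (factor, level, tau, bin, rate, v) for export."""
    rows = []
    for u in units:
        for b in range(len(u.rate)):
            rows.append((u.factor, u.level, u.tau, b, u.rate[b], u.v[b]))
    return pd.DataFrame(rows, columns=["factor", "level", "tau", "bin", "rate", "v"])
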