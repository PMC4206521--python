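"""Reoxygenation observables: peaks, oscillation onset, peak/baseline ratios.

After reoxygenation the nuclear HiF-1α level first dips (degradation resumes
abruptly) and then overshoots in a damped oscillation driven by the
pVHL-feedback loop.  The observables extracted here are the ones used to
characterize that response: the delay from the oxygen switch to the first
qualifying peak (the oscillation onset), the highest post-switch level
relative to the normoxic baseline, and the early time-to-minimum, reported
separately from the onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import Trajectory

__all__ = [
    "Peak",
    "PeakList",
    "find_peaks",
    "oscillation_onset",
    "time_to_minimum",
    "peak_to_baseline_ratio",
    "DEFAULT_PROMINENCE_FRACTION",
]

#: Default peak prominence, as a fraction of the normoxic baseline.
DEFAULT_PROMINENCE_FRACTION = 0.01


@dataclass(frozen=True)
class Peak:
    time: float
    value: float
    prominence: float


@dataclass(frozen=True)
class PeakList:
    """Ordered local maxima of one species' series."""

    peaks: tuple[Peak, ...]

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.peaks])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.peaks])


def find_peaks(
    trajectory: Trajectory,
    species: str = "nuclear_hif",
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    baseline: float | None = None,
) -> PeakList:
    """Local maxima with prominence ≥ ``prominence_fraction`` × baseline.

    ``baseline`` defaults to the series' initial value (the pre-perturbation
    level for protocol trajectories).  Endpoints are never reported as
    peaks; series shorter than 3 samples are invalid.
    """
    if not (0.0 < prominence_fraction < 1.0):
        raise ValueError(
            f"prominence_fraction must be in (0, 1), got {prominence_fraction}"
        )
    y = trajectory.series(species)
    if y.size < 3:
        raise ValueError(f"series has {y.size} samples; need >= 3")
    if baseline is None:
        baseline = float(y[0])
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    idx, props = signal.find_peaks(y, prominence=prominence_fraction * baseline)
    peaks = tuple(
        Peak(float(trajectory.times[i]), float(y[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    )
    return PeakList(peaks)


def oscillation_onset(
    trajectory: Trajectory,
    species: str = "nuclear_hif",
    t_event: float | None = None,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    baseline: float | None = None,
) -> float | None:
    """Delay from ``t_event`` to the first qualifying peak after it.

    ``t_event`` defaults to the trajectory's ``"reoxygenation"`` event
    marker.  Returns None when no peak follows the event (explicit
    no-oscillation result).
    """
    t_event = _resolve_event(trajectory, t_event)
    peaks = find_peaks(trajectory, species, prominence_fraction, baseline)
    after = [p for p in peaks if p.time > t_event]
    if not after:
        return None
    return after[0].time - t_event


def time_to_minimum(
    trajectory: Trajectory,
    species: str = "nuclear_hif",
    t_event: float | None = None,
) -> float:
    """Delay from ``t_event`` to the first post-event minimum of the series.

    Captures the sudden early dip after reoxygenation, reported separately
    from the oscillation onset.
    """
    t_event = _resolve_event(trajectory, t_event)
    mask = trajectory.times >= t_event
    y = trajectory.series(species)[mask]
    t = trajectory.times[mask]
    minima, _ = signal.find_peaks(-y)
    if minima.size:
        return float(t[minima[0]] - t_event)
    return float(t[np.argmin(y)] - t_event)


def peak_to_baseline_ratio(
    trajectory: Trajectory,
    species: str = "nuclear_hif",
    t_event: float | None = None,
    baseline: float | None = None,
) -> float:
    """Maximum of the series after ``t_event`` divided by ``baseline``.

    ``baseline`` defaults to the series' initial value (for protocol runs,
    the normoxic equilibrium level).
    """
    t_event = _resolve_event(trajectory, t_event)
    if baseline is None:
        baseline = float(trajectory.series(species)[0])
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    mask = trajectory.times >= t_event
    return float(trajectory.series(species)[mask].max() / baseline)


def _resolve_event(trajectory: Trajectory, t_event: float | None) -> float:
    if t_event is None:
        if "reoxygenation" in trajectory.events:
            t_event = trajectory.events["reoxygenation"]
        else:
            t_event = 0.0
    if not (trajectory.times[0] <= t_event <= trajectory.times[-1]):
        raise ValueError(
            f"t_event = {t_event} is outside the trajectory span "
            f"[{trajectory.times[0]}, {trajectory.times[-1]}]"
        )
    return float(t_event)
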