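"""Integration of the model under the experimental protocols.

Protocols mirror the bench experiments the model is meant to reproduce:

* ``steady_state`` — long relaxation from a near-empty cell, polished by a
  damped Newton step, with detection of oscillatory attractors.
* ``cycloheximide_chase`` — protein synthesis blockade in normoxia
  (``k_syn_hif`` = ``k_transl`` = 0 from the normoxic stationary state).
* ``hypoxia_step`` — drop of the complex-formation rate from the normoxic
  stationary state.
* ``reoxygenation_protocol`` — a hypoxic interval followed by restoration of
  the normoxic complex-formation rate.
* ``single_compartment_control`` — the same protocol with the shuttle removed
  (``k_export`` = ``k_import`` = 0) and the cytoplasm emptied, i.e. a
  non-compartmentalized version of the model.

The system is stiff (complex dissociation at 7200 h⁻¹ against mRNA turnover
at 0.6 h⁻¹ spans four decades), so the integrator is LSODA at rtol 1e-8 /
atol 1e-10 nM, restarted exactly at every discontinuity of the oxygen
schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import rhs
from .params import (
    KineticParameters,
    NORMOXIC_K_FORM,
    STATE_FIELDS,
    SystemState,
)

__all__ = [
    "OxygenSchedule",
    "Trajectory",
    "SteadyStateResult",
    "IntegrationError",
    "NoStationaryStateError",
    "integrate",
    "steady_state",
    "cycloheximide_chase",
    "hypoxia_step",
    "reoxygenation_protocol",
    "single_compartment_control",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # nM

#: Relaxation horizon used to locate stationary states (h).
_SS_T_END = 2000.0
#: Window over which oscillatory attractors are detected (h).
_SS_OSC_WINDOW = 200.0
#: Relative peak-to-peak amplitude above which the attractor is declared
#: oscillatory rather than stationary.
_SS_OSC_THRESHOLD = 1e-4


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the failure time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g} h)")
        self.t_fail = t_fail


class NoStationaryStateError(RuntimeError):
    """A stationary state was required but the attractor is not a fixed point."""


@dataclass(frozen=True)
class OxygenSchedule:
    """Piecewise-constant complex-formation rate k_form(t), right-continuous.

    ``breakpoints`` is an ordered sequence of ``(t_start, k_form_value)``
    pairs; the first entry must start at t = 0.
    """

    breakpoints: tuple

    def __post_init__(self):
        bp = tuple((float(t), float(k)) for t, k in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if not bp:
            raise ValueError("schedule needs at least one breakpoint")
        if bp[0][0] != 0.0:
            raise ValueError(f"first breakpoint must start at t = 0, got {bp[0][0]}")
        times = [t for t, _ in bp]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(k < 0 for _, k in bp):
            raise ValueError("k_form values must be >= 0")

    @classmethod
    def constant(cls, k_form_value: float) -> "OxygenSchedule":
        return cls(((0.0, k_form_value),))

    @classmethod
    def step(cls, k_first: float, t_switch: float, k_second: float) -> "OxygenSchedule":
        return cls(((0.0, k_first), (t_switch, k_second)))

    def k_form_at(self, t: float) -> float:
        value = self.breakpoints[0][1]
        for t_start, k in self.breakpoints:
            if t >= t_start:
                value = k
            else:
                break
        return value

    def segments(self, t_end: float):
        """Yield ``(t0, t1, k_form)`` pieces covering [0, t_end]."""
        starts = [t for t, _ in self.breakpoints if t < t_end]
        values = [k for t, k in self.breakpoints if t < t_end]
        bounds = starts + [t_end]
        for (t0, t1), k in zip(zip(bounds, bounds[1:]), values):
            yield t0, t1, k


@dataclass
class Trajectory:
    """A simulated time course on a regular output grid.

    Attributes
    ----------
    times : ndarray, hours, strictly increasing, starting at 0.
    states : ndarray of shape (len(times), 7), columns in ``STATE_FIELDS``
        order.
    schedule : OxygenSchedule applied during the run.
    params : KineticParameters snapshot.
    events : dict of named event times (e.g. ``{"reoxygenation": 30.0}``).
    """

    times: np.ndarray
    states: np.ndarray
    schedule: OxygenSchedule
    params: KineticParameters
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(STATE_FIELDS)):
            raise ValueError(
                f"state matrix shape {self.states.shape} does not match "
                f"{self.times.size} times x {len(STATE_FIELDS)} species"
            )

    # ---- derived series -------------------------------------------------
    @property
    def hif_total(self) -> np.ndarray:
        Y = self.states
        return Y[:, 0] + Y[:, 1] + Y[:, 5] + Y[:, 6]

    @property
    def nuclear_hif(self) -> np.ndarray:
        """Nuclear HiF-1α, free plus complexed."""
        return self.states[:, 0] + self.states[:, 5]

    @property
    def cytoplasmic_hif(self) -> np.ndarray:
        """Cytoplasmic HiF-1α, free plus complexed."""
        return self.states[:, 1] + self.states[:, 6]

    @property
    def k_form_applied(self) -> np.ndarray:
        return np.array([self.schedule.k_form_at(t) for t in self.times])

    def series(self, species: str) -> np.ndarray:
        """A named series: any raw field or a derived total."""
        derived = {
            "hif_total": lambda: self.hif_total,
            "nuclear_hif": lambda: self.nuclear_hif,
            "cytoplasmic_hif": lambda: self.cytoplasmic_hif,
        }
        if species in derived:
            return derived[species]()
        if species in STATE_FIELDS:
            return self.states[:, STATE_FIELDS.index(species)]
        raise KeyError(
            f"unknown species {species!r}; expected one of "
            f"{STATE_FIELDS + tuple(derived)}"
        )

    def initial_state(self) -> SystemState:
        return SystemState.from_array(self.states[0])

    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with the canonical CSV columns."""
        data = {"t_h": self.times}
        for i, name in enumerate(STATE_FIELDS):
            data[name] = self.states[:, i]
        data["hif_total"] = self.hif_total
        data["k_form_applied"] = self.k_form_applied
        return pd.DataFrame(data)

    def plot(self, species=("nuclear_hif", "cytoplasmic_hif"), ax=None):
        """Convenience time-course plot (returns the matplotlib axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in species:
            ax.plot(self.times, self.series(name), label=name)
        for label, t in self.events.items():
            ax.axvline(t, color="grey", ls="--", lw=0.8)
            ax.annotate(label, (t, ax.get_ylim()[1]), fontsize=8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (nM)")
        ax.legend()
        return ax


def _solve_segment(p, y0, t0, t1, k_form, t_eval, rtol, atol, max_step):
    sol = solve_ivp(
        lambda t, y: rhs(y, p, k_form),
        (t0, t1),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        max_step=max_step,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", sol.t[-1] if sol.t.size else t0)
    return sol


def integrate(
    params: KineticParameters,
    initial_state: SystemState,
    schedule: OxygenSchedule,
    t_end: float,
    dt_out: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = np.inf,
    events: dict | None = None,
) -> Trajectory:
    """Integrate the model on the regular grid {0, dt_out, …, t_end}.

    Integration restarts exactly at every schedule breakpoint so the
    discontinuity in k_form is never smoothed across.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if dt_out <= 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")

    n_out = int(round(t_end / dt_out))
    t_end = n_out * dt_out
    grid = np.linspace(0.0, t_end, n_out + 1)

    y = initial_state.to_array()
    times = [0.0]
    states = [y.copy()]
    for t0, t1, k_form in schedule.segments(t_end):
        inner = grid[(grid > t0 + 1e-12) & (grid < t1 - 1e-12)]
        t_eval = np.concatenate([inner, [t1]])
        sol = _solve_segment(params, y, t0, t1, k_form, t_eval, rtol, atol, max_step)
        y = sol.y[:, -1].copy()
        # keep only the regular grid points (segment ends that fall off-grid
        # are used as restart states but not emitted)
        on_grid = np.abs(sol.t / dt_out - np.round(sol.t / dt_out)) < 1e-6
        times.extend(sol.t[on_grid])
        states.extend(sol.y[:, on_grid].T)

    T = np.array(times)
    Y = np.array(states)
    # negative-concentration guard: tolerate integrator-level undershoot only
    floor = -10.0 * atol
    if Y.min() < floor:
        i, j = np.unravel_index(np.argmin(Y), Y.shape)
        raise IntegrationError(
            f"species {STATE_FIELDS[j]} went negative ({Y[i, j]:.3e} nM)", T[i]
        )
    np.clip(Y, 0.0, None, out=Y)
    return Trajectory(T, Y, schedule, params, events=dict(events or {}))


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of a stationary-state search.

    ``status`` is ``"converged"``, ``"oscillatory"`` (the attractor is a
    limit cycle — reported as a result, not an exception) or
    ``"not-converged"``.
    """

    status: str
    state: SystemState | None
    residual_norm: float
    k_form_value: float

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def require(self) -> SystemState:
        """The stationary state, or an informative error if there is none."""
        if not self.converged:
            raise NoStationaryStateError(
                f"no stationary state at k_form = {self.k_form_value:g}: "
                f"status {self.status!r}, residual {self.residual_norm:.2e} nM/h"
            )
        return self.state

    @property
    def nuclear_hif(self) -> float:
        s = self.require()
        return s.hif_nuc + s.cplx_nuc

    @property
    def cytoplasmic_hif(self) -> float:
        s = self.require()
        return s.hif_cyt + s.cplx_cyt

    @property
    def total_hif(self) -> float:
        s = self.require()
        return s.hif_nuc + s.hif_cyt + s.cplx_nuc + s.cplx_cyt


def steady_state(
    params: KineticParameters,
    k_form_value: float,
    *,
    initial_state: SystemState | None = None,
    t_relax: float = _SS_T_END,
    residual_tol: float = 1e-9,
) -> SteadyStateResult:
    """Stationary state at a fixed complex-formation rate.

    Procedure: relax from a near-empty cell (1e-3 nM everywhere, or the
    supplied warm start) for ``t_relax`` hours, test the final 200 h window
    for sustained oscillation of nuclear HiF-1α, then polish the endpoint
    with a damped Newton step on the algebraic system.  Convergence requires
    the sup-norm of the vector field below ``residual_tol`` nM·h⁻¹.
    """
    if k_form_value < 0:
        raise ValueError(f"k_form_value must be >= 0, got {k_form_value}")
    y0 = (initial_state or SystemState.uniform(1e-3)).to_array()

    f = lambda y: rhs(y, params, k_form_value)
    sol = solve_ivp(
        lambda t, y: f(y), (0.0, t_relax), y0, method="LSODA",
        rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
        t_eval=np.linspace(t_relax - _SS_OSC_WINDOW, t_relax, 401),
    )
    if not sol.success:
        return SteadyStateResult("not-converged", None, np.inf, k_form_value)
    tail = sol.y[0] + sol.y[5]  # nuclear HiF over the detection window
    ptp = float(tail.max() - tail.min())
    # relative extrema spread, with an absolute floor so that empty cells
    # (mean ~ 0) are not mistaken for limit cycles
    if ptp > max(_SS_OSC_THRESHOLD * tail.mean(), 100.0 * DEFAULT_ATOL):
        return SteadyStateResult("oscillatory", None, ptp, k_form_value)

    y_end = sol.y[:, -1]
    polish = root(f, y_end, method="hybr", tol=1e-13)
    y_star = polish.x if polish.success and polish.x.min() > -1e-9 else y_end
    y_star = np.clip(y_star, 0.0, None)
    res = float(np.max(np.abs(f(y_star))))
    if res >= residual_tol:
        return SteadyStateResult("not-converged", None, res, k_form_value)
    return SteadyStateResult(
        "converged", SystemState.from_array(y_star), res, k_form_value
    )


def cycloheximide_chase(
    params: KineticParameters,
    t_end: float = 6.0,
    dt_out: float = 1.0 / 60.0,
) -> Trajectory:
    """Protein-synthesis blockade from the normoxic stationary state.

    HiF-1α synthesis and pVHL translation are set to zero and the decay of
    total HiF-1α is recorded; 6 h at 1-min sampling by default, matching the
    window on which the bi-exponential degradation law is fitted.
    """
    eq = steady_state(params, params.k_form).require()
    chase_params = params.replace(k_syn_hif=0.0, k_transl=0.0)
    return integrate(
        chase_params, eq, OxygenSchedule.constant(params.k_form), t_end, dt_out,
        events={"chase_start": 0.0},
    )


def hypoxia_step(
    params: KineticParameters,
    k_form_hypoxic: float,
    t_end: float = 30.0,
    dt_out: float = 0.01,
) -> Trajectory:
    """Switch to a hypoxic complex-formation rate at t = 0.

    The initial condition is the normoxic stationary state (k_form = 1000).
    """
    if k_form_hypoxic >= NORMOXIC_K_FORM:
        warnings.warn(
            f"k_form_hypoxic = {k_form_hypoxic:g} is not below the normoxic "
            f"value {NORMOXIC_K_FORM:g}; this is not a hypoxic perturbation",
            stacklevel=2,
        )
    eq = steady_state(params, NORMOXIC_K_FORM).require()
    return integrate(
        params, eq, OxygenSchedule.constant(k_form_hypoxic), t_end, dt_out,
        events={"hypoxia_onset": 0.0},
    )


def reoxygenation_protocol(
    params: KineticParameters,
    k_form_hypoxic: float,
    hypoxia_duration: float = 30.0,
    t_end_after: float = 30.0,
    dt_out: float = 0.01,
) -> Trajectory:
    """Hypoxic interval followed by restoration of the normoxic rate.

    Starts from the normoxic stationary state, holds ``k_form_hypoxic`` for
    ``hypoxia_duration`` hours (long enough, at the default 30 h, for the
    system to settle into its hypoxic stationary state) and then restores
    k_form = 1000.  The reoxygenation instant is recorded as an event marker.
    """
    if hypoxia_duration <= 0:
        raise ValueError(f"hypoxia_duration must be > 0, got {hypoxia_duration}")
    eq = steady_state(params, NORMOXIC_K_FORM).require()
    schedule = OxygenSchedule.step(k_form_hypoxic, hypoxia_duration, NORMOXIC_K_FORM)
    return integrate(
        params, eq, schedule, hypoxia_duration + t_end_after, dt_out,
        events={"reoxygenation": hypoxia_duration},
    )


def single_compartment_control(
    params: KineticParameters,
    k_form_hypoxic: float,
    hypoxia_duration: float = 30.0,
    t_end_after: float = 30.0,
    dt_out: float = 0.01,
) -> Trajectory:
    """Non-compartmentalized control of the reoxygenation protocol.

    The shuttle is removed (k_export = k_import = 0) and all cytoplasmic
    species start at zero, leaving a single effective nuclear compartment.
    With no influx terms the cytoplasmic species remain identically zero.
    """
    p0 = params.replace(k_export=0.0, k_import=0.0, free_pvhl_shuttles=False)
    eq = steady_state(p0, NORMOXIC_K_FORM).require()
    y = eq.to_array().copy()
    y[[1, 3, 6]] = 0.0  # empty the cytoplasm exactly
    schedule = OxygenSchedule.step(k_form_hypoxic, hypoxia_duration, NORMOXIC_K_FORM)
    return integrate(
        p0, SystemState.from_array(y), schedule,
        hypoxia_duration + t_end_after, dt_out,
        events={"reoxygenation": hypoxia_duration},
    )
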