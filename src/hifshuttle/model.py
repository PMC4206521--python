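"""Mass-action vector field of the seven-ODE model and its conservation laws.

Writing h for free HiF-1α, v for free pVHL, c for the complex, m for pVHL
mRNA, with compartment subscripts n (nucleus) and c (cytoplasm), the field is

    dh_n/dt = k_syn − α·h_n − k_form·h_n·v_n + k_dis·c_n + β·c_n
    dh_c/dt =       − α·h_c − k_form·h_c·v_c + k_dis·c_c + β·c_c
    dm/dt   = k_fb·driver − β_m·m
    dv_n/dt = k_tl·m − β·v_n − k_form·h_n·v_n + k_dis·c_n + (γ_n + α)·c_n
    dv_c/dt =        − β·v_c − k_form·h_c·v_c + k_dis·c_c + (γ_c + α)·c_c
    dc_n/dt = k_form·h_n·v_n − (k_dis + α + β + γ_n)·c_n − k_exp·c_n + k_imp·c_c
    dc_c/dt = k_form·h_c·v_c − (k_dis + α + β + γ_c)·c_c + k_exp·c_n − k_imp·c_c

HiF-1α is synthesised in the nucleus, pVHL is translated into the nucleus,
and only the complex shuttles by default (``free_pvhl_shuttles`` adds the
mirror shuttle terms to the free pVHL equations).  Degrading HiF-1α (α, γ)
releases the bound pVHL; degrading pVHL (β) releases the bound HiF-1α.

Summing the HiF-bearing species gives the conservation identity that the
mass-balance check below enforces numerically:

    d/dt (h_n + h_c + c_n + c_c) = k_syn − α·(total HiF) − γ_n·c_n − γ_c·c_c
"""

from __future__ import annotations

import numpy as np

from .params import (
    InvalidStateError,
    KineticParameters,
    StateDerivative,
    SystemState,
)

__all__ = [
    "derivative_field",
    "rhs",
    "total_hif",
    "total_pvhl",
    "mass_balance_residuals",
    "HifVhlModel",
]


def rhs(y: np.ndarray, p: KineticParameters, k_form_now: float) -> np.ndarray:
    """Raw right-hand side on a 7-vector ``[h_n, h_c, v_n, v_c, m, c_n, c_c]``.

    The hot path used by the integrators; does no validation.
    """
    hn, hc, vn, vc, m, cn, cc = y
    a = p.alpha_deg_hif
    b = p.beta_deg_vhl
    form_n = k_form_now * hn * vn
    form_c = k_form_now * hc * vc
    driver = hn if p.mrna_driver == "nuclear_free_hif" else hn + hc + cn + cc

    dhn = p.k_syn_hif - a * hn - form_n + p.k_dis * cn + b * cn
    dhc = -a * hc - form_c + p.k_dis * cc + b * cc
    dm = p.k_feedback * driver - p.beta_deg_mrna * m
    dvn = p.k_transl * m - b * vn - form_n + p.k_dis * cn + (p.gamma_nuc + a) * cn
    dvc = -b * vc - form_c + p.k_dis * cc + (p.gamma_cyt + a) * cc
    dcn = (form_n - (p.k_dis + a + b + p.gamma_nuc) * cn
           - p.k_export * cn + p.k_import * cc)
    dcc = (form_c - (p.k_dis + a + b + p.gamma_cyt) * cc
           + p.k_export * cn - p.k_import * cc)
    if p.free_pvhl_shuttles:
        dvn += -p.k_export * vn + p.k_import * vc
        dvc += p.k_export * vn - p.k_import * vc
    return np.array([dhn, dhc, dvn, dvc, dm, dcn, dcc])


def derivative_field(
    state: SystemState, params: KineticParameters, k_form_now: float
) -> StateDerivative:
    """Instantaneous derivative of the system at ``state``.

    Pure function; raises :class:`InvalidStateError` on negative
    concentrations and ``ValueError`` on a negative rate.
    """
    if k_form_now < 0 or not np.isfinite(k_form_now):
        raise ValueError(f"k_form_now must be a finite rate >= 0, got {k_form_now!r}")
    return StateDerivative.from_array(rhs(state.to_array(), params, k_form_now))


def total_hif(state: SystemState) -> float:
    """Total HiF-1α: free plus complexed, both compartments (nM)."""
    return state.hif_nuc + state.hif_cyt + state.cplx_nuc + state.cplx_cyt


def total_pvhl(state: SystemState) -> float:
    """Total pVHL protein: free plus complexed, both compartments (nM)."""
    return state.vhl_nuc + state.vhl_cyt + state.cplx_nuc + state.cplx_cyt


def mass_balance_residuals(trajectory, params: KineticParameters | None = None):
    """Residuals of the HiF and pVHL conservation identities along a trajectory.

    For each stored time point, compares the numerical time-derivative of the
    conserved totals with the net source terms implied by the reaction
    scheme:

    * HiF:  d/dt(total HiF) − [k_syn − α·totalHiF − γ_n·c_n − γ_c·c_c]
    * pVHL: d/dt(total pVHL) − [k_tl·m − β·totalpVHL]

    Both residuals vanish identically on an exact solution; on an adaptive
    numerical solution they are bounded by the differentiation error of the
    output grid.

    Returns
    -------
    (hif_residual, vhl_residual) : tuple of ndarray
        One value per trajectory time point, in nM·h⁻¹.
    """
    if params is None:
        params = trajectory.params
    t = np.asarray(trajectory.times)
    if t.size < 3:
        raise ValueError("mass balance needs a trajectory with >= 3 time points")
    Y = np.asarray(trajectory.states)  # (n_times, 7)
    hif_tot = Y[:, 0] + Y[:, 1] + Y[:, 5] + Y[:, 6]
    vhl_tot = Y[:, 2] + Y[:, 3] + Y[:, 5] + Y[:, 6]

    hif_source = (params.k_syn_hif - params.alpha_deg_hif * hif_tot
                  - params.gamma_nuc * Y[:, 5] - params.gamma_cyt * Y[:, 6])
    vhl_source = params.k_transl * Y[:, 4] - params.beta_deg_vhl * vhl_tot

    hif_res = _differentiate(trajectory, t, hif_tot) - hif_source
    vhl_res = _differentiate(trajectory, t, vhl_tot) - vhl_source
    return hif_res, vhl_res


def _differentiate(trajectory, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Numerical d/dt of a stored series, never across a schedule breakpoint.

    Uniform segments use a high-order local-polynomial (Savitzky–Golay)
    derivative so the discretisation error stays far below the physical
    fluxes; non-uniform grids fall back to second-order differences.
    """
    from scipy.signal import savgol_filter

    schedule = getattr(trajectory, "schedule", None)
    breaks = [bt for bt, _ in schedule.breakpoints[1:]] if schedule is not None else []
    edges = np.searchsorted(t, np.asarray(breaks) - 1e-12)
    bounds = [0, *edges.tolist(), t.size]

    out = np.empty_like(y)
    for a, b in zip(bounds, bounds[1:]):
        if b - a < 2:
            out[a:b] = 0.0
            continue
        ts, ys = t[a:b], y[a:b]
        dt = np.diff(ts)
        if b - a >= 9 and np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            out[a:b] = savgol_filter(ys, 9, 7, deriv=1, delta=dt[0])
        else:
            out[a:b] = np.gradient(ys, ts)
    return out


def max_interior_residual(trajectory, params: KineticParameters | None = None,
                          guard: int = 8) -> float:
    """Largest mass-balance residual away from grid edges and switches.

    The residual series is exact only where the numerical derivative is
    well-posed: ``guard`` samples are discarded at both ends of every
    schedule segment, where one-sided stencils meet the under-resolved
    re-equilibration layer of the fast complex pools (rates ~k_dis).
    Returns the max over both conservation identities, in nM·h⁻¹.
    """
    hif_res, vhl_res = mass_balance_residuals(trajectory, params)
    t = np.asarray(trajectory.times)
    schedule = getattr(trajectory, "schedule", None)
    breaks = [bt for bt, _ in schedule.breakpoints[1:]] if schedule is not None else []
    edges = np.searchsorted(t, np.asarray(breaks) - 1e-12)
    bounds = [0, *edges.tolist(), t.size]
    keep = np.zeros(t.size, dtype=bool)
    for a, b in zip(bounds, bounds[1:]):
        if b - a > 2 * guard:
            keep[a + guard:b - guard] = True
    if not keep.any():
        raise ValueError("trajectory too short for the interior-residual guard")
    return float(max(np.abs(hif_res[keep]).max(), np.abs(vhl_res[keep]).max()))


class HifVhlModel:
    """The compartmental HiF-1α/pVHL model for one parameter set.

    A thin object-oriented front end: protocol methods return
    :class:`~hifshuttle.simulate.Trajectory` objects, steady states return
    :class:`~hifshuttle.simulate.SteadyStateResult`.

    Examples
    --------
    >>> from hifshuttle import HifVhlModel, KineticParameters
    >>> model = HifVhlModel(KineticParameters())
    >>> eq = model.steady_state().require()
    >>> round(eq.hif_nuc + eq.cplx_nuc)   # nuclear HiF-1α, nM
    140
    """

    def __init__(self, params: KineticParameters | None = None):
        self.params = params if params is not None else KineticParameters()

    def derivative(self, state: SystemState, k_form_now: float | None = None):
        if k_form_now is None:
            k_form_now = self.params.k_form
        return derivative_field(state, self.params, k_form_now)

    def steady_state(self, k_form_value: float | None = None, **kw):
        from .simulate import steady_state
        if k_form_value is None:
            k_form_value = self.params.k_form
        return steady_state(self.params, k_form_value, **kw)

    def integrate(self, initial_state, schedule, t_end, dt_out, **kw):
        from .simulate import integrate
        return integrate(self.params, initial_state, schedule, t_end, dt_out, **kw)

    def cycloheximide_chase(self, **kw):
        from .simulate import cycloheximide_chase
        return cycloheximide_chase(self.params, **kw)

    def hypoxia_step(self, k_form_hypoxic, **kw):
        from .simulate import hypoxia_step
        return hypoxia_step(self.params, k_form_hypoxic, **kw)

    def reoxygenation(self, k_form_hypoxic, **kw):
        from .simulate import reoxygenation_protocol
        return reoxygenation_protocol(self.params, k_form_hypoxic, **kw)

    def single_compartment_control(self, k_form_hypoxic, **kw):
        from .simulate import single_compartment_control
        return single_compartment_control(self.params, k_form_hypoxic, **kw)

    def __repr__(self) -> str:
        return f"HifVhlModel({self.params!r})"
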