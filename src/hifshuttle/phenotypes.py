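"""Equilibrium sweeps, switch thresholds and mutation/therapy scenarios.

The complex-formation rate stands in for oxygen tension, so equilibrium
sweeps over ``k_form`` trace the accumulation of HiF-1α as oxygen falls, and
two-parameter maps over (``k_form``, ``k_export``) or (``k_syn_hif``,
``k_export``) place cell types — slowly proliferating (high pVHL export) vs
proliferating (low export) — and tumor genotypes on a common diagram.
Scenario presets encode the tumor and therapy cases: transcriptional
HiF-1α overexpression (synthesis rate multiplied), pVHL loss-of-function as
in renal clear-cell carcinoma (complex-formation rate divided), siRNA
knockdown (synthesis rate set to an absolute value) and proteasome boosting
(both pVHL-dependent degradation rates multiplied jointly).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import KineticParameters, NORMOXIC_K_FORM
from .simulate import steady_state

__all__ = [
    "ScenarioKind",
    "ScenarioSpec",
    "apply_scenario",
    "apply_preset",
    "SCENARIO_PRESETS",
    "EquilibriumMap",
    "equilibrium_accumulation_curve",
    "localization_map",
    "nuclear_switch_threshold",
    "fold_change_vs_reference",
]


class ScenarioKind(str, enum.Enum):
    KS_OVEREXPRESSION = "KS_OVEREXPRESSION"
    PVHL_MUTATION = "PVHL_MUTATION"
    SIRNA_KS = "SIRNA_KS"
    PROTEASOME_BOOST = "PROTEASOME_BOOST"
    IDENTITY = "IDENTITY"


@dataclass(frozen=True)
class ScenarioSpec:
    """One parameter transformation.

    ``magnitude`` is a fold for KS_OVEREXPRESSION (multiplies the synthesis
    rate) and PROTEASOME_BOOST (multiplies both pVHL-dependent degradation
    rates jointly), a divisor for PVHL_MUTATION (divides the
    complex-formation rate), and an absolute synthesis rate (nM·h⁻¹) for
    SIRNA_KS.
    """

    kind: ScenarioKind
    magnitude: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "kind", ScenarioKind(self.kind))
        if self.magnitude <= 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")


def apply_scenario(params: KineticParameters, scenario: ScenarioSpec) -> KineticParameters:
    """Pure transformation of a parameter set; unrelated fields untouched."""
    kind, m = scenario.kind, scenario.magnitude
    if kind is ScenarioKind.IDENTITY:
        return params
    if kind is ScenarioKind.KS_OVEREXPRESSION:
        return params.replace(k_syn_hif=params.k_syn_hif * m)
    if kind is ScenarioKind.PVHL_MUTATION:
        return params.replace(k_form=params.k_form / m)
    if kind is ScenarioKind.SIRNA_KS:
        return params.replace(k_syn_hif=m)
    if kind is ScenarioKind.PROTEASOME_BOOST:
        return params.replace(gamma_nuc=params.gamma_nuc * m,
                              gamma_cyt=params.gamma_cyt * m)
    raise ValueError(f"unhandled scenario kind {kind!r}")  # pragma: no cover


#: Named composites used by the tumor/therapy analyses.
SCENARIO_PRESETS: dict[str, tuple[ScenarioSpec, ...]] = {
    "normal": (ScenarioSpec(ScenarioKind.IDENTITY),),
    # peritoneal-cancer-like overexpression: synthesis rate tripled
    "peritoneal": (ScenarioSpec(ScenarioKind.KS_OVEREXPRESSION, 3.0),),
    "peritoneal_proteasome_therapy": (
        ScenarioSpec(ScenarioKind.KS_OVEREXPRESSION, 3.0),
        ScenarioSpec(ScenarioKind.PROTEASOME_BOOST, 10.0),
    ),
    # renal clear-cell carcinoma: pVHL loss-of-function
    "rcc": (ScenarioSpec(ScenarioKind.PVHL_MUTATION, 100.0),),
    "rcc_sirna_therapy": (
        ScenarioSpec(ScenarioKind.PVHL_MUTATION, 100.0),
        ScenarioSpec(ScenarioKind.SIRNA_KS, 200.0),
    ),
    # tumor cell used in the reoxygenation comparison: synthesis rate 5000
    "tumor_reoxygenation": (ScenarioSpec(ScenarioKind.KS_OVEREXPRESSION, 5.0),),
}


def apply_preset(params: KineticParameters, name: str) -> KineticParameters:
    if name not in SCENARIO_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(SCENARIO_PRESETS)}"
        )
    for spec in SCENARIO_PRESETS[name]:
        params = apply_scenario(params, spec)
    return params


def _equilibrium(params: KineticParameters, k_form: float, warm=None):
    return steady_state(params, k_form, initial_state=warm)


def equilibrium_accumulation_curve(params: KineticParameters, k_form_values) -> pd.DataFrame:
    """Nuclear and cytoplasmic equilibrium HiF-1α vs complex-formation rate.

    One stationary state per value; rows in input order; non-convergent
    points are masked with a reason instead of being interpolated.
    """
    k_form_values = np.asarray(k_form_values, dtype=float)
    if np.any(k_form_values <= 0):
        raise ValueError("k_form values must be > 0")
    rows = []
    for k in k_form_values:
        res = steady_state(params, float(k))
        if res.converged:
            rows.append({
                "k_form": k,
                "nuclear_hif": res.nuclear_hif,
                "cytoplasmic_hif": res.cytoplasmic_hif,
                "total_hif": res.total_hif,
                "converged": True,
                "reason": "",
            })
        else:
            rows.append({
                "k_form": k, "nuclear_hif": np.nan, "cytoplasmic_hif": np.nan,
                "total_hif": np.nan, "converged": False, "reason": res.status,
            })
    return pd.DataFrame(rows)


@dataclass
class EquilibriumMap:
    """Two-parameter equilibrium map.

    ``ratio_total`` is total HiF-1α normalized to the reference cell;
    ``ratio_nc`` the nuclear/cytoplasmic ratio; both at steady state.  Cells
    where no stationary state exists are masked (NaN, ``converged`` False).
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    ratio_total: np.ndarray   # shape (len(axis1), len(axis2))
    ratio_nc: np.ndarray
    converged: np.ndarray
    reference_total: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (axis1, axis2, R, R_nc, converged)."""
        rows = []
        for i, a in enumerate(self.axis1_values):
            for j, b in enumerate(self.axis2_values):
                rows.append({
                    self.axis1_name: a,
                    self.axis2_name: b,
                    "ratio_total": self.ratio_total[i, j],
                    "ratio_nc": self.ratio_nc[i, j],
                    "converged": bool(self.converged[i, j]),
                })
        return pd.DataFrame(rows)


def localization_map(
    params: KineticParameters,
    k_form_grid,
    k_export_grid,
    reference_cell: KineticParameters | None = None,
) -> EquilibriumMap:
    """Total-accumulation and localization map over (k_form, k_export).

    The reference cell defaults to the normoxic, slowly proliferating cell
    (k_form = 1000, k_export = 1000 under default parameters); ``R`` is total
    HiF-1α over the reference total, ``R_nc`` the nuclear/cytoplasmic ratio.
    """
    k_form_grid = np.asarray(k_form_grid, dtype=float)
    k_export_grid = np.asarray(k_export_grid, dtype=float)
    if k_form_grid.size == 0 or k_export_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(k_form_grid <= 0) or np.any(k_export_grid <= 0):
        raise ValueError("grid values must be > 0")

    ref = reference_cell or params
    ref_res = steady_state(ref, ref.k_form).require()
    ref_total = (ref_res.hif_nuc + ref_res.hif_cyt
                 + ref_res.cplx_nuc + ref_res.cplx_cyt)

    shape = (k_form_grid.size, k_export_grid.size)
    R = np.full(shape, np.nan)
    Rnc = np.full(shape, np.nan)
    ok = np.zeros(shape, dtype=bool)
    for i, kf in enumerate(k_form_grid):
        for j, ke in enumerate(k_export_grid):
            res = steady_state(params.replace(k_export=float(ke)), float(kf))
            if res.converged:
                R[i, j] = res.total_hif / ref_total
                cyt = res.cytoplasmic_hif
                Rnc[i, j] = res.nuclear_hif / cyt if cyt > 0 else np.inf
                ok[i, j] = True
    return EquilibriumMap(
        "k_form", k_form_grid, "k_export", k_export_grid, R, Rnc, ok, ref_total
    )


def nuclear_switch_threshold(
    params: KineticParameters,
    criterion_fold: float = 2.0,
    bracket: tuple[float, float] = (1e-3, 1e3),
    tol: float = 1e-3,
) -> float | None:
    """Complex-formation rate below which nuclear HiF-1α has accumulated.

    Defined as the k_form at which the nuclear equilibrium level reaches
    ``criterion_fold`` times its normoxic (k_form = 1000) value, located by
    bisection in log k_form.  Returns None if the criterion is never met
    inside the bracket (explicit not-found result).
    """
    if criterion_fold <= 1:
        raise ValueError(f"criterion_fold must be > 1, got {criterion_fold}")
    baseline = steady_state(params, NORMOXIC_K_FORM).require()
    target = criterion_fold * (baseline.hif_nuc + baseline.cplx_nuc)

    def excess(k):
        res = steady_state(params, k)
        if not res.converged:
            return np.nan
        return res.nuclear_hif - target

    lo, hi = bracket
    f_lo, f_hi = excess(lo), excess(hi)
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)):
        return None
    if f_lo < 0 or f_hi > 0:
        # accumulation never reaches the criterion (or never falls below it)
        return None
    while np.log(hi / lo) > tol:
        mid = np.sqrt(lo * hi)
        f_mid = excess(mid)
        if not np.isfinite(f_mid):
            return None
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def fold_change_vs_reference(
    variant: KineticParameters,
    reference: KineticParameters,
    compartment: str = "nuclear",
) -> float:
    """Steady-state HiF-1α level of ``variant`` over that of ``reference``.

    ``compartment`` is ``"nuclear"``, ``"cytoplasmic"`` or ``"total"``
    (free + complexed in all cases).  Non-convergence raises an error naming
    the offending side.
    """
    if compartment not in ("nuclear", "cytoplasmic", "total"):
        raise ValueError(f"unknown compartment {compartment!r}")
    levels = {}
    for label, p in (("variant", variant), ("reference", reference)):
        res = steady_state(p, p.k_form)
        if not res.converged:
            raise RuntimeError(
                f"the {label} parameter set has no stationary state "
                f"(status {res.status!r})"
            )
        levels[label] = getattr(res, f"{compartment}_hif" if compartment != "total"
                                else "total_hif")
    return levels["variant"] / levels["reference"]
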