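"""Constraint-based simulation: FBA and parsimonious FBA.

Flux balance analysis maximizes the biomass reaction's flux subject to
steady state (S·v = 0), reaction bounds, and medium uptake limits; the
biomass flux is the in-silico specific growth rate (h⁻¹).  A total-carbon
uptake cap (c-mmol gCDW⁻¹ h⁻¹) can be imposed across all open exchange
reactions: uptake is measured with nonnegative split variables so that
secretion can never relax the cap (consumption, not net exchange, is
capped).  Parsimonious FBA (pFBA) then fixes the biomass optimum and
minimizes total absolute flux, removing futile cycles from the reported
distribution.

Both problems are linear programs solved with HiGHS (scipy.optimize.linprog)
under a fixed lexicographic variable ordering, so repeated runs return
identical flux vectors whenever the optimum is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix, csr_matrix

from .model_core import Model, carbon_count

__all__ = [
    "MediumSpec",
    "FluxSolution",
    "solve_fba",
    "solve_pfba",
    "growth_test",
    "DEFAULT_GROWTH_THRESHOLD",
]

DEFAULT_GROWTH_THRESHOLD = 1e-6  # h^-1; numerically-safe "growth" cutoff
_UNBOUNDED_UPTAKE = 1000.0  # mmol gCDW^-1 h^-1, standard COBRA default


@dataclass
class MediumSpec:
    """Environmental condition for a simulation.

    ``uptake`` maps exchange reaction ids to maximum uptake rates
    (mmol gCDW⁻¹ h⁻¹); ``always_open`` exchanges (water, protons, O₂,
    phosphate, sulfate, ammonium, trace/vitamin proxies) get unbounded
    uptake; every other exchange is closed for uptake.  Secretion is never
    restricted by the medium.  ``carbon_cap``, when set, bounds the summed
    carbon uptake (uptake flux × carbon atoms of the exchanged metabolite)
    in c-mmol gCDW⁻¹ h⁻¹.
    """

    uptake: dict[str, float] = field(default_factory=dict)
    carbon_cap: float | None = None
    always_open: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rxn_id, limit in self.uptake.items():
            if limit < 0:
                raise ValueError(f"uptake limit for {rxn_id} must be >= 0")
        if self.carbon_cap is not None and self.carbon_cap <= 0:
            raise ValueError("carbon_cap must be > 0 when set")

    @classmethod
    def from_dict(cls, data: dict) -> "MediumSpec":
        return cls(
            uptake={k: float(v) for k, v in data.get("uptake", {}).items()},
            carbon_cap=(
                float(data["carbon_cap"]) if data.get("carbon_cap") is not None
                else None
            ),
            always_open=set(data.get("always_open", [])),
        )


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | failed
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    total_flux: float | None = None
    residual: float | None = None  # ||S v||_inf at the returned point

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction\tflux\n")
            for rxn_id in sorted(self.fluxes):
                fh.write(f"{rxn_id}\t{self.fluxes[rxn_id]:.10g}\n")


def _effective_bounds(model: Model, medium: MediumSpec) -> dict[str, tuple[float, float]]:
    """Reaction bounds with the medium applied to exchange lower bounds."""
    for rxn_id in medium.uptake:
        if rxn_id not in model.reactions:
            raise ValueError(f"medium names unknown exchange reaction {rxn_id}")
    bounds: dict[str, tuple[float, float]] = {}
    for rxn_id, rxn in model.reactions.items():
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange:
            if rxn_id in medium.uptake:
                lb = -medium.uptake[rxn_id]
            elif rxn_id in medium.always_open:
                lb = -_UNBOUNDED_UPTAKE
            else:
                lb = 0.0  # uptake closed; secretion keeps the model's ub
        bounds[rxn_id] = (lb, ub)
    return bounds


def _exchange_carbon(model: Model) -> dict[str, int]:
    """Carbon atoms of the metabolite each exchange reaction exchanges.

    Metabolites without a recorded formula contribute zero carbon (they
    cannot be counted; the carbon cap is then a lower bound on consumption).
    """
    out: dict[str, int] = {}
    for rxn in model.reactions.values():
        if not rxn.is_exchange:
            continue
        (met_id,) = rxn.stoichiometry
        formula = model.metabolites[met_id].formula
        out[rxn.id] = carbon_count(formula) if formula else 0
    return out


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_fba(
    model: Model,
    medium: MediumSpec,
    objective: str | None = None,
) -> FluxSolution:
    """Maximize the biomass flux under steady state, bounds, medium and cap."""
    obj_id = objective or model.objective
    if obj_id is None or obj_id not in model.reactions:
        raise ValueError(f"model {model.id} has no usable objective reaction")

    rxn_ids = sorted(model.reactions)
    ridx = {r: i for i, r in enumerate(rxn_ids)}
    met_ids = sorted(model.metabolites)
    midx = {m: i for i, m in enumerate(met_ids)}
    n = len(rxn_ids)

    rows, cols, vals = [], [], []
    for rxn_id in rxn_ids:
        for met_id, coeff in model.reactions[rxn_id].stoichiometry.items():
            rows.append(midx[met_id])
            cols.append(ridx[rxn_id])
            vals.append(coeff)
    eff = _effective_bounds(model, medium)

    capped: list[str] = []
    carbon = _exchange_carbon(model)
    if medium.carbon_cap is not None:
        capped = [
            r for r in rxn_ids
            if model.reactions[r].is_exchange and carbon.get(r, 0) > 0
            and eff[r][0] < 0
        ]
    n_aux = len(capped)
    n_var = n + n_aux

    A_eq = csr_matrix(
        coo_matrix((vals, (rows, cols)), shape=(len(met_ids), n_var))
    )
    b_eq = np.zeros(len(met_ids))

    # u_e >= -v_e  <=>  -v_e - u_e <= 0 ; sum_e c_e u_e <= cap
    ub_rows, ub_cols, ub_vals, b_ub = [], [], [], []
    for k, rxn_id in enumerate(capped):
        ub_rows += [k, k]
        ub_cols += [ridx[rxn_id], n + k]
        ub_vals += [-1.0, -1.0]
        b_ub.append(0.0)
    if capped:
        row = len(capped)
        for k, rxn_id in enumerate(capped):
            ub_rows.append(row)
            ub_cols.append(n + k)
            ub_vals.append(float(carbon[rxn_id]))
        b_ub.append(float(medium.carbon_cap))
    A_ub = (
        csr_matrix(coo_matrix((ub_vals, (ub_rows, ub_cols)),
                              shape=(len(b_ub), n_var)))
        if b_ub else None
    )

    bounds = [eff[r] for r in rxn_ids] + [(0.0, None)] * n_aux
    c = np.zeros(n_var)
    c[ridx[obj_id]] = -1.0

    res = linprog(
        c, A_ub=A_ub, b_ub=np.array(b_ub) if b_ub else None,
        A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)
    v = res.x[:n]
    residual = float(np.max(np.abs(A_eq[:, :n] @ v))) if len(met_ids) else 0.0
    return FluxSolution(
        status="optimal",
        objective_value=float(v[ridx[obj_id]]),
        fluxes={r: float(v[ridx[r]]) for r in rxn_ids},
        residual=residual,
    )


def solve_pfba(
    model: Model,
    medium: MediumSpec,
    objective: str | None = None,
    biomass_tolerance: float = 1e-6,
) -> FluxSolution:
    """Parsimonious FBA: hold the FBA optimum, minimize total |flux|.

    The absolute values are linearized by splitting each flux into
    nonnegative forward/reverse parts; the carbon cap is enforced on the
    reverse (uptake) parts of the exchange reactions.
    """
    fba = solve_fba(model, medium, objective)
    if not fba.optimal:
        return fba
    obj_id = objective or model.objective
    opt = fba.objective_value

    rxn_ids = sorted(model.reactions)
    ridx = {r: i for i, r in enumerate(rxn_ids)}
    met_ids = sorted(model.metabolites)
    midx = {m: i for i, m in enumerate(met_ids)}
    n = len(rxn_ids)
    n_var = 3 * n  # v, p (forward part), q (reverse part)

    rows, cols, vals = [], [], []
    for rxn_id in rxn_ids:
        for met_id, coeff in model.reactions[rxn_id].stoichiometry.items():
            rows.append(midx[met_id])
            cols.append(ridx[rxn_id])
            vals.append(coeff)
    # v - p + q = 0
    for i in range(n):
        base = len(met_ids) + i
        rows += [base, base, base]
        cols += [i, n + i, 2 * n + i]
        vals += [1.0, -1.0, 1.0]
    A_eq = csr_matrix(
        coo_matrix((vals, (rows, cols)), shape=(len(met_ids) + n, n_var))
    )
    b_eq = np.zeros(len(met_ids) + n)

    eff = _effective_bounds(model, medium)
    # pin biomass essentially at the optimum; the slack only absorbs solver
    # round-off and stays far inside the documented relative tolerance
    slack = max(1e-3 * biomass_tolerance * abs(opt), 1e-9)
    bounds: list[tuple[float, float | None]] = []
    for r in rxn_ids:
        lb, ub = eff[r]
        if r == obj_id:
            lb = opt - slack
            ub = min(ub, opt + slack) if ub is not None else opt + slack
        bounds.append((lb, ub))
    bounds += [(0.0, None)] * (2 * n)

    # carbon cap on the reverse (uptake) parts of carbon exchanges
    b_ub: list[float] = []
    ub_rows, ub_cols, ub_vals = [], [], []
    if medium.carbon_cap is not None:
        carbon = _exchange_carbon(model)
        capped = [
            r for r in rxn_ids
            if model.reactions[r].is_exchange and carbon.get(r, 0) > 0
        ]
        if capped:
            for rxn_id in capped:
                ub_rows.append(0)
                ub_cols.append(2 * n + ridx[rxn_id])
                ub_vals.append(float(carbon[rxn_id]))
            b_ub.append(float(medium.carbon_cap))
    A_ub = (
        csr_matrix(coo_matrix((ub_vals, (ub_rows, ub_cols)),
                              shape=(len(b_ub), n_var)))
        if b_ub else None
    )

    c = np.zeros(n_var)
    c[n:] = 1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=np.array(b_ub) if b_ub else None,
        A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)
    v = res.x[:n]
    S = A_eq[: len(met_ids), :n]
    residual = float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0
    return FluxSolution(
        status="optimal",
        objective_value=float(v[ridx[obj_id]]),
        fluxes={r: float(v[ridx[r]]) for r in rxn_ids},
        total_flux=float(np.sum(res.x[n:])),
        residual=residual,
    )


def growth_test(
    model: Model,
    medium: MediumSpec,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> bool:
    """True iff FBA is optimal with biomass flux strictly above ``threshold``."""
    sol = solve_fba(model, medium)
    return sol.optimal and sol.objective_value > threshold
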