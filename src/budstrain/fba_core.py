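"""Flux balance analysis core: LP solves, FVA, envelopes, knockouts, yields.

All optimization reduces to linear programs of the form

    optimize  c . v   subject to   S v = 0,   lb <= v <= ub

solved with HiGHS through :func:`scipy.optimize.linprog`.  The environment
(uptake bounds and the ATP maintenance demand) is a set of bound overrides
applied on top of the model's own bounds; by convention exchange flux is
negative for uptake, so a glucose uptake rate of 10 mmol/gDCW/h is the bound
pair [-10, 0] on the glucose exchange reaction.

Degenerate optima are handled lexicographically: "production at maximal
growth" always means optimizing growth first, fixing it, then optimizing the
product flux (:func:`fix_and_optimize`), never whatever vertex one LP solve
happens to return.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_io import MetabolicModel, classify_reaction

logger = logging.getLogger("budstrain")

#: molar masses in g/mol used for flux -> mass-yield conversion
MOLAR_MASS = {
    "2,3-butanediol": 90.121,
    "glucose": 180.156,
    "ethanol": 46.068,
    "glycerol": 92.094,
    "acetate": 60.052,
}

#: default LP feasibility/optimality tolerances
LP_TOL = 1e-9
#: mass-balance tolerance asserted on optimal flux vectors
MASS_BALANCE_TOL = 1e-6


class EnvironmentError_(ValueError):
    pass


@dataclass(frozen=True)
class EnvironmentSpec:
    """Uptake and maintenance constraints, all in mmol/gDCW/h.

    ``uptakes`` maps exchange reaction ids to uptake bounds (negative =
    uptake: the value becomes the exchange lower bound, the upper bound is
    left untouched).  ``maintenance`` maps the maintenance pseudo-reaction id
    to its minimum flux (a lower bound; the upper bound is left open so
    excess ATP can be dissipated).
    """

    uptakes: dict[str, float] = field(default_factory=dict)
    maintenance: dict[str, float] = field(default_factory=dict)

    def validate(self, model: MetabolicModel) -> None:
        for rid in self.uptakes:
            if rid not in model.reaction_index:
                raise EnvironmentError_(f"uptake bound for unknown reaction {rid!r}")
            if classify_reaction(model, rid) != "exchange":
                raise EnvironmentError_(f"uptake bound on non-exchange reaction {rid!r}")
        for rid, lb in self.maintenance.items():
            if rid not in model.reaction_index:
                raise EnvironmentError_(f"maintenance bound for unknown reaction {rid!r}")
            if classify_reaction(model, rid) != "maintenance":
                raise EnvironmentError_(f"maintenance bound on non-maintenance reaction {rid!r}")
            if lb < 0:
                raise EnvironmentError_(f"maintenance lower bound must be >= 0, got {lb}")

    def apply(self, model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
        """Model bounds with the environment's overrides applied."""
        self.validate(model)
        lb, ub = model.bounds()
        ridx = model.reaction_index
        for rid, val in self.uptakes.items():
            lb[ridx[rid]] = float(val)
        for rid, val in self.maintenance.items():
            lb[ridx[rid]] = float(val)
        return lb, ub


#: the constraint set used for all simulations: glucose uptake 10, oxygen
#: uptake 2, ATP maintenance 1 (mmol/gDCW/h)
def default_environment(
    glucose_exchange: str = "EX_glc_e",
    oxygen_exchange: str = "EX_o2_e",
    maintenance_id: str = "ATPM",
) -> EnvironmentSpec:
    return EnvironmentSpec(
        uptakes={glucose_exchange: -10.0, oxygen_exchange: -2.0},
        maintenance={maintenance_id: 1.0},
    )


@dataclass
class FluxDistribution:
    """One steady-state flux vector with objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    objective_id: str | None = None
    #: dual objective reconstructed from the solver's multipliers (optimal only)
    dual_objective: float | None = None

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class InfeasibleProblemError(RuntimeError):
    pass


def _solve_lp(
    S: sp.csr_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    sense: str,
) -> tuple[str, np.ndarray | None, float | None, float | None]:
    """Solve optimize c.v st S v = 0, lb <= v <= ub.  Returns (status, v,
    objective, dual objective)."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL, "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status == 2:
        return "infeasible", None, None, None
    if res.status == 3:
        return "unbounded", None, None, None
    if res.status != 0:  # pragma: no cover - numerical failure
        raise RuntimeError(f"LP solver failure: {res.message}")
    # dual objective of the solved (min) problem: b_eq is zero, so only the
    # bound multipliers contribute; flip sign back for maximization
    finite_l = np.where(np.isfinite(lb), lb, 0.0)
    finite_u = np.where(np.isfinite(ub), ub, 0.0)
    dual = float(res.lower.marginals @ finite_l + res.upper.marginals @ finite_u)
    return "optimal", res.x, float(sign * res.fun), float(sign * dual)


def solve_fba(
    model: MetabolicModel,
    env: EnvironmentSpec,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimize one reaction flux at steady state.

    ``objective_id`` defaults to the model's declared objective (biomass).
    Infeasible or unbounded problems are reported in ``status`` with no flux
    vector, never raised.
    """
    objective_id = objective_id or model.objective_id
    j = model.reaction_index[objective_id]
    S = model.stoichiometric_matrix()
    lb, ub = env.apply(model)
    c = np.zeros(len(model.reactions))
    c[j] = 1.0
    status, v, obj, dual = _solve_lp(S, lb, ub, c, sense)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status,
                                objective_id=objective_id)
    imbalance = np.abs(S @ v).max() if S.shape[0] else 0.0
    if imbalance > MASS_BALANCE_TOL:  # pragma: no cover - solver contract
        raise RuntimeError(f"mass balance violated: ||S v||_inf = {imbalance:g}")
    return FluxDistribution(
        fluxes={r.id: float(v[i]) for i, r in enumerate(model.reactions)},
        objective_value=obj,
        status="optimal",
        objective_id=objective_id,
        dual_objective=dual,
    )


def fix_and_optimize(
    model: MetabolicModel,
    env: EnvironmentSpec,
    primary_id: str,
    secondary_id: str,
    sense: str = "max",
    primary_sense: str = "max",
) -> FluxDistribution:
    """Lexicographic two-stage optimization.

    Stage 1 optimizes ``primary_id`` (the cellular objective, growth); stage 2
    fixes that optimum within ``1e-9 * max(1, |opt|)`` and optimizes
    ``secondary_id`` with ``sense``.  This is how every reported "production
    at maximal growth" value is computed.
    """
    S = model.stoichiometric_matrix()
    lb, ub = env.apply(model)
    n = len(model.reactions)
    jp = model.reaction_index[primary_id]
    js = model.reaction_index[secondary_id]

    c1 = np.zeros(n)
    c1[jp] = 1.0
    status, v, opt, _ = _solve_lp(S, lb, ub, c1, primary_sense)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status,
                                objective_id=secondary_id)

    tol = 1e-9 * max(1.0, abs(opt))
    lb2, ub2 = lb.copy(), ub.copy()
    if primary_sense == "max":
        lb2[jp] = max(lb2[jp], opt - tol)
    else:
        ub2[jp] = min(ub2[jp], opt + tol)
    c2 = np.zeros(n)
    c2[js] = 1.0
    status, v, obj, dual = _solve_lp(S, lb2, ub2, c2, sense)
    if status != "optimal":  # pragma: no cover - fixing a feasible optimum stays feasible
        return FluxDistribution(fluxes={}, objective_value=None, status=status,
                                objective_id=secondary_id)
    return FluxDistribution(
        fluxes={r.id: float(v[i]) for i, r in enumerate(model.reactions)},
        objective_value=obj,
        status="optimal",
        objective_id=secondary_id,
        dual_objective=dual,
    )


def solve_fva(
    model: MetabolicModel,
    env: EnvironmentSpec,
    reaction_ids: list[str],
    growth_fraction: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis at a fixed fraction of maximal growth.

    For each listed reaction, solves the min and max LP with the biomass flux
    constrained to at least ``growth_fraction`` times its optimum.  With
    ``growth_fraction=1`` the ranges describe the optimal face.
    """
    if not 0.0 <= growth_fraction <= 1.0:
        raise ValueError(f"growth_fraction must be in [0, 1], got {growth_fraction}")
    if not reaction_ids:
        return {}
    S = model.stoichiometric_matrix()
    lb, ub = env.apply(model)
    n = len(model.reactions)
    jb = model.reaction_index[model.objective_id]
    cb = np.zeros(n)
    cb[jb] = 1.0
    status, _, gmax, _ = _solve_lp(S, lb, ub, cb, "max")
    if status != "optimal":
        raise InfeasibleProblemError(f"base FBA problem is {status}")
    lb2 = lb.copy()
    lb2[jb] = max(lb2[jb], growth_fraction * gmax - 1e-9 * max(1.0, abs(gmax)))
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        j = model.reaction_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        _, _, lo, _ = _solve_lp(S, lb2, ub, c, "min")
        _, _, hi, _ = _solve_lp(S, lb2, ub, c, "max")
        out[rid] = (float(lo), float(hi))
    return out


@dataclass(frozen=True)
class ProductionEnvelope:
    """Min/max attainable target flux as a function of growth.

    ``points`` is an ordered list of (growth, target_min, target_max) triples
    over an equispaced growth grid from 0 to the maximal growth rate.  A
    collapsed envelope (min == max > 0) at the right edge indicates
    growth-coupled production.
    """

    target_id: str
    points: tuple[tuple[float, float, float], ...]

    @property
    def growth_coupled(self) -> bool:
        g, lo, hi = self.points[-1]
        return lo > 1e-9


def production_envelope(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    n_points: int = 20,
) -> ProductionEnvelope:
    """Compute the production envelope of ``target_id`` over a growth grid."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    S = model.stoichiometric_matrix()
    lb, ub = env.apply(model)
    n = len(model.reactions)
    jb = model.reaction_index[model.objective_id]
    jt = model.reaction_index[target_id]
    cb = np.zeros(n)
    cb[jb] = 1.0
    status, _, gmax, _ = _solve_lp(S, lb, ub, cb, "max")
    if status != "optimal":
        raise InfeasibleProblemError(f"base FBA problem is {status}")
    if gmax <= 1e-12:
        logger.warning("maximal growth is zero; envelope collapses to one point")
        grid = np.array([0.0])
    else:
        grid = np.linspace(0.0, gmax, n_points)
    ct = np.zeros(n)
    ct[jt] = 1.0
    pts = []
    for g in grid:
        # growth is constrained from below; at the right edge this coincides
        # with the optimal face, and at g=0 the envelope spans the whole
        # feasible flux cone of the target
        tol = 1e-9 * max(1.0, abs(g))
        lb2 = lb.copy()
        lb2[jb] = max(lb[jb], g - tol)
        _, _, lo, _ = _solve_lp(S, lb2, ub, ct, "min")
        _, _, hi, _ = _solve_lp(S, lb2, ub, ct, "max")
        pts.append((float(g), float(lo), float(hi)))
    return ProductionEnvelope(target_id=target_id, points=tuple(pts))


def apply_knockouts(
    model: MetabolicModel,
    reactions: set[str] | frozenset[str] = frozenset(),
    genes: set[str] | frozenset[str] = frozenset(),
) -> tuple[MetabolicModel, frozenset[str]]:
    """Derived model with the listed reactions and gene-implied reactions zeroed.

    Reaction knockouts set lb = ub = 0 directly.  Gene knockouts zero every
    reaction whose GPR evaluates false with those genes deleted.  Returns the
    derived copy and the set of all zeroed reaction ids; the input model is
    untouched.  Unknown ids raise before any mutation.
    """
    unknown_r = set(reactions) - set(model.reaction_index)
    if unknown_r:
        raise KeyError(f"unknown reaction ids {sorted(unknown_r)}")
    unknown_g = set(genes) - set(model.genes)
    if unknown_g:
        raise KeyError(f"unknown gene ids {sorted(unknown_g)}")
    zeroed = set(reactions)
    if genes:
        for r in model.reactions:
            if not r.gpr.is_always_on and not r.gpr.evaluate(set(genes)):
                zeroed.add(r.id)
    derived = model.with_bounds({rid: (0.0, 0.0) for rid in zeroed})
    return derived, frozenset(zeroed)


@dataclass(frozen=True)
class YieldReport:
    """Mass yield of a product on a substrate, Y = v_t MW_t / (|v_s| MW_s)."""

    target_flux: float
    substrate_flux: float
    mw_target: float
    mw_substrate: float

    @property
    def mass_yield(self) -> float:
        return (self.target_flux * self.mw_target) / (abs(self.substrate_flux) * self.mw_substrate)


def flux_to_mass_yield(
    v_target: float,
    v_substrate: float,
    mw_target: float = MOLAR_MASS["2,3-butanediol"],
    mw_substrate: float = MOLAR_MASS["glucose"],
) -> YieldReport:
    """Convert molar fluxes (mmol/gDCW/h) to a g/g mass yield report.

    Substrate flux may carry the uptake sign convention (negative); its
    magnitude is used.  Zero substrate flux is a division error.
    """
    if v_substrate == 0:
        raise ZeroDivisionError("substrate flux is zero; mass yield undefined")
    return YieldReport(
        target_flux=float(v_target),
        substrate_flux=float(v_substrate),
        mw_target=float(mw_target),
        mw_substrate=float(mw_substrate),
    )
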