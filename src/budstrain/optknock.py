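"""OptKnock: bilevel knockout design as a single-level MILP via LP duality.

The bilevel program chooses up to K reaction knockouts (binary activity
indicators y, y=0 = knocked out) to maximize a product flux, while the inner
problem is the cell's own FBA: maximize growth subject to S v = 0 and bounds.
Inner optimality is enforced in a single level by adding the inner dual's
feasibility constraints together with the strong-duality equality

    c_inner . v  =  sum_j ( ub_j mu^ub_j  -  lb_j mu^lb_j )

where for knockout candidates the bilinear products y * mu are replaced by
auxiliary variables z with a big-M linearization.  Because big-M MILPs can
silently lie when M truncates the dual space, every returned strategy is
re-verified with independent LPs (:func:`verify_strategy`) before it is
returned.

Candidate knockouts follow the published screening rules: exchange and
transport reactions are never targets, nor are the biomass and maintenance
pseudo-reactions; essential reactions (single knockout drops growth below
the viability floor) and blocked reactions are removed before the MILP.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .fba_core import (
    EnvironmentSpec,
    MOLAR_MASS,
    ProductionEnvelope,
    apply_knockouts,
    fix_and_optimize,
    flux_to_mass_yield,
    production_envelope,
    solve_fba,
    solve_fva,
)
from .model_io import MetabolicModel, classify_reaction, minimal_gene_knockouts

logger = logging.getLogger("budstrain")


@dataclass(frozen=True)
class OptKnockConfig:
    """Settings for one OptKnock run.

    ``f_min`` is the minimum-growth viability floor; given as a fraction of
    the wild-type optimum via ``f_min_fraction`` (default 5%) unless an
    absolute value ``f_min_absolute`` is supplied.  ``big_M`` must dominate
    every candidate bound magnitude.
    """

    K: int = 1
    candidates: tuple[str, ...] | None = None
    f_min_fraction: float = 0.05
    f_min_absolute: float | None = None
    big_M: float = 1000.0
    mip_gap: float = 1e-6
    ban: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("knockout budget K must be >= 0")
        if self.f_min_absolute is not None and self.f_min_absolute < 0:
            raise ValueError("f_min must be >= 0")

    def resolve_f_min(self, wild_type_growth: float) -> float:
        if self.f_min_absolute is not None:
            return self.f_min_absolute
        return self.f_min_fraction * wild_type_growth


@dataclass(frozen=True)
class KnockoutStrategy:
    """A deletion strategy with its independently verified predictions."""

    reactions: tuple[str, ...]
    growth: float
    target_flux_max: float
    target_flux_min: float
    yield_g_per_g: float
    gene_sets: tuple[frozenset[str], ...] = ()
    solver_gap: float | None = None


@dataclass(frozen=True)
class VerificationRecord:
    """Independent LP re-check of a strategy's claimed performance."""

    reactions: tuple[str, ...]
    growth: float
    target_flux_max: float
    target_flux_min: float
    yield_g_per_g: float
    envelope: ProductionEnvelope | None
    flags: tuple[str, ...] = ()


class NoStrategyError(RuntimeError):
    """The MILP admits no strategy at the given K / viability floor."""


def build_candidate_set(
    model: MetabolicModel,
    env: EnvironmentSpec,
    f_min: float,
) -> tuple[list[str], dict[str, str]]:
    """Knockout candidates with per-reaction exclusion reasons.

    Keeps internal reactions only (exchange, transport, biomass and
    maintenance are excluded by kind), then removes reactions essential at
    ``f_min`` (their single knockout drops maximal growth below the floor or
    makes the problem infeasible) and blocked reactions (zero FVA range with
    no growth requirement).
    """
    reasons: dict[str, str] = {}
    internal = []
    for r in model.reactions:
        kind = classify_reaction(model, r.id)
        if kind != "internal":
            reasons[r.id] = f"excluded: kind={kind}"
        else:
            internal.append(r.id)

    if not internal:
        logger.warning("model %s has no internal reactions; candidate set is empty", model.id)
        return [], reasons

    ranges = solve_fva(model, env, internal, growth_fraction=0.0)
    candidates = []
    for rid in internal:
        lo, hi = ranges[rid]
        if max(abs(lo), abs(hi)) <= 1e-9:
            reasons[rid] = "excluded: blocked (zero flux range)"
            continue
        ko_model, _ = apply_knockouts(model, reactions={rid})
        sol = solve_fba(ko_model, env)
        growth = sol.objective_value if sol.optimal else 0.0
        if growth < f_min:
            reasons[rid] = f"excluded: essential at f_min={f_min:g} (knockout growth {growth:g})"
            continue
        reasons[rid] = "candidate"
        candidates.append(rid)
    if not candidates:
        logger.warning("candidate set for model %s is empty after screening", model.id)
    return sorted(candidates), reasons


def _lexicographic_eval(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    deleted: frozenset[str],
    f_min: float,
) -> tuple[float, float] | None:
    """(growth, lexicographic max target flux) after deletions, or None if the
    strategy is infeasible or below the viability floor."""
    ko_model, _ = apply_knockouts(model, reactions=set(deleted))
    sol = solve_fba(ko_model, env)
    if not sol.optimal or sol.objective_value < f_min - 1e-9:
        return None
    lexi = fix_and_optimize(ko_model, env, ko_model.objective_id, target_id, sense="max")
    return float(sol.objective_value), float(lexi.objective_value)


def _prune_deletions(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    deleted: frozenset[str],
    f_min: float,
    achieved_target: float,
) -> frozenset[str]:
    """Drop deletions that do not contribute to the achieved target flux.

    The MILP may set y=0 on reactions whose removal is gratuitous (budget
    slack); the tie-break 'fewer knockouts first' is realized by greedily
    reactivating any deletion whose removal keeps the lexicographic target
    within tolerance.
    """
    current = set(deleted)
    changed = True
    while changed:
        changed = False
        for rid in sorted(current):
            trial = frozenset(current - {rid})
            res = _lexicographic_eval(model, env, target_id, trial, f_min)
            if res is not None and res[1] >= achieved_target - 1e-7:
                current.remove(rid)
                changed = True
                break
    return frozenset(current)


def _build_and_solve_milp(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    candidates: list[str],
    K: int,
    f_min: float,
    big_M: float,
    mip_gap: float,
    integer_cuts: list[frozenset[str]],
) -> tuple[frozenset[str], float, float] | None:
    """Solve the single-level OptKnock MILP.

    Returns (deleted reaction set, outer objective, MIP gap) or None when the
    MILP is infeasible.  Variable layout: v (n) | y (q binary) | lambda (m) |
    mu_ub (n) | mu_lb (n) | z_ub (q) | z_lb (q).
    """
    S = model.stoichiometric_matrix().tocsc()
    lb, ub = env.apply(model)
    n = len(model.reactions)
    m = len(model.metabolites)
    ridx = model.reaction_index
    cand_idx = [ridx[rid] for rid in candidates]
    q = len(candidates)
    if big_M < max((max(abs(lb[j]), abs(ub[j])) for j in cand_idx), default=0.0):
        raise ValueError("big_M must be >= the largest candidate bound magnitude")

    jb = ridx[model.objective_id]
    jt = ridx[target_id]
    c_inner = np.zeros(n)
    c_inner[jb] = 1.0

    # offsets into the variable vector
    off_v, off_y = 0, n
    off_lam = off_y + q
    off_mub = off_lam + m
    off_mlb = off_mub + n
    off_zub = off_mlb + n
    off_zlb = off_zub + q
    nvar = off_zlb + q

    rows_A, lo_list, hi_list = [], [], []

    def add(coefs: dict[int, float], lo: float, hi: float):
        rows_A.append(coefs)
        lo_list.append(lo)
        hi_list.append(hi)

    # steady state: S v = 0
    Scoo = S.tocoo()
    srows: dict[int, dict[int, float]] = {i: {} for i in range(m)}
    for i, j, val in zip(Scoo.row, Scoo.col, Scoo.data):
        srows[i][off_v + j] = srows[i].get(off_v + j, 0.0) + val
    for i in range(m):
        add(srows[i], 0.0, 0.0)

    # candidate bound linking: lb_j y_j <= v_j <= ub_j y_j
    for k, j in enumerate(cand_idx):
        add({off_v + j: 1.0, off_y + k: -ub[j]}, -np.inf, 0.0)
        add({off_v + j: 1.0, off_y + k: -lb[j]}, 0.0, np.inf)

    # inner dual feasibility: S^T lambda + mu_ub - mu_lb = c_inner
    ST = S.T.tocoo()
    drows: dict[int, dict[int, float]] = {j: {} for j in range(n)}
    for j, i, val in zip(ST.row, ST.col, ST.data):
        drows[j][off_lam + i] = drows[j].get(off_lam + i, 0.0) + val
    for j in range(n):
        drows[j][off_mub + j] = 1.0
        drows[j][off_mlb + j] = -1.0
        add(drows[j], c_inner[j], c_inner[j])

    # z linearization for candidates: z = y * mu within [0, M]
    for k in range(q):
        for off_z, off_mu in ((off_zub, off_mub), (off_zlb, off_mlb)):
            j = cand_idx[k]
            add({off_z + k: 1.0, off_y + k: -big_M}, -np.inf, 0.0)          # z <= M y
            add({off_z + k: 1.0, off_mu + j: -1.0}, -np.inf, 0.0)          # z <= mu
            add({off_mu + j: 1.0, off_z + k: -1.0, off_y + k: big_M}, -np.inf, big_M)  # z >= mu - M(1-y)

    # strong duality: c_inner . v - sum_j (ub_j mu_ub_j - lb_j mu_lb_j) = 0,
    # with z replacing y*mu on candidate positions
    sd: dict[int, float] = {off_v + jb: 1.0}
    cand_set = set(cand_idx)
    for j in range(n):
        if j in cand_set:
            k = cand_idx.index(j)
            sd[off_zub + k] = sd.get(off_zub + k, 0.0) - ub[j]
            sd[off_zlb + k] = sd.get(off_zlb + k, 0.0) + lb[j]
        else:
            sd[off_mub + j] = sd.get(off_mub + j, 0.0) - ub[j]
            sd[off_mlb + j] = sd.get(off_mlb + j, 0.0) + lb[j]
    add(sd, 0.0, 0.0)

    # knockout budget: sum (1 - y) <= K  <=>  sum y >= q - K
    add({off_y + k: 1.0 for k in range(q)}, q - K, np.inf)

    # viability: growth >= f_min
    add({off_v + jb: 1.0}, f_min, np.inf)

    # integer cuts: forbid previously returned deletion sets (and supersets);
    # the empty deletion set is forbidden by requiring at least one knockout
    for cut in integer_cuts:
        if not cut:
            add({off_y + k: 1.0 for k in range(q)}, -np.inf, q - 1)
            continue
        coefs = {off_y + candidates.index(rid): 1.0 for rid in cut if rid in candidates}
        if coefs:
            add(coefs, 1.0, np.inf)

    # assemble sparse constraint matrix
    data, ri, ci = [], [], []
    for r, coefs in enumerate(rows_A):
        for cidx, val in coefs.items():
            ri.append(r)
            ci.append(cidx)
            data.append(val)
    A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows_A), nvar))

    # variable bounds
    vlo = np.full(nvar, -np.inf)
    vhi = np.full(nvar, np.inf)
    vlo[off_v:off_v + n] = lb
    vhi[off_v:off_v + n] = ub
    vlo[off_y:off_y + q] = 0.0
    vhi[off_y:off_y + q] = 1.0
    vlo[off_mub:off_mub + n] = 0.0
    vhi[off_mub:off_mub + n] = big_M
    vlo[off_mlb:off_mlb + n] = 0.0
    vhi[off_mlb:off_mlb + n] = big_M
    vlo[off_zub:] = 0.0
    vhi[off_zub:] = big_M

    integrality = np.zeros(nvar)
    integrality[off_y:off_y + q] = 1.0

    c_outer = np.zeros(nvar)
    c_outer[off_v + jt] = -1.0  # milp minimizes

    from scipy.optimize import Bounds

    res = milp(
        c=c_outer,
        constraints=LinearConstraint(A, np.array(lo_list), np.array(hi_list)),
        integrality=integrality,
        bounds=Bounds(vlo, vhi),
        options={"mip_rel_gap": mip_gap},
    )
    if not res.success:
        return None
    y = res.x[off_y:off_y + q]
    deleted = frozenset(candidates[k] for k in range(q) if y[k] < 0.5)
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    return deleted, float(-res.fun), gap


def solve_optknock(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    config: OptKnockConfig,
) -> KnockoutStrategy:
    """Run OptKnock and return the best verified knockout strategy.

    The MILP's claimed production is confirmed with independent lexicographic
    LPs before the strategy is returned; gratuitous deletions (budget slack)
    are pruned so ties resolve to fewer knockouts.
    """
    strategies = enumerate_alternatives(model, env, target_id, config, n_solutions=1)
    return strategies[0]


def enumerate_alternatives(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    config: OptKnockConfig,
    n_solutions: int = 1,
) -> list[KnockoutStrategy]:
    """Enumerate distinct strategies with integer cuts.

    Each solve adds a cut forbidding the previous deletion set, so no
    strategy is returned twice.  Strategies come back ordered by outer
    objective descending, ties by fewer knockouts then lexicographic ids.
    Exhaustion before ``n_solutions`` yields a shorter list.
    """
    if n_solutions < 1:
        raise ValueError("n_solutions must be >= 1")
    if target_id not in model.reaction_index:
        raise KeyError(f"unknown target reaction {target_id!r}")

    wt = solve_fba(model, env)
    if not wt.optimal:
        raise NoStrategyError(f"wild-type FBA is {wt.status}; no strategy exists")
    f_min = config.resolve_f_min(wt.objective_value)
    if wt.objective_value < f_min - 1e-9:
        raise NoStrategyError(
            f"viability floor f_min={f_min:g} exceeds the wild-type optimum "
            f"{wt.objective_value:g}; no strategy can satisfy it"
        )

    if config.candidates is not None:
        candidates = sorted(config.candidates)
    else:
        candidates, _ = build_candidate_set(model, env, f_min)
    candidates = [c for c in candidates if c not in config.ban]

    def lp_record(deleted: frozenset[str]) -> VerificationRecord:
        return verify_strategy(
            model, env, target_id,
            KnockoutStrategy(reactions=tuple(sorted(deleted)), growth=np.nan,
                             target_flux_max=np.nan, target_flux_min=np.nan,
                             yield_g_per_g=np.nan),
            envelope_points=0,
        )

    out: list[KnockoutStrategy] = []
    seen: set[frozenset[str]] = set()
    cuts: list[frozenset[str]] = []
    # distinct MILP solutions can prune to the same deletion set; allow a few
    # extra solves so duplicates are skipped rather than returned
    max_iterations = 5 * n_solutions + 5
    for _ in range(max_iterations):
        if len(out) >= n_solutions:
            break
        if config.K == 0 or not candidates:
            if cuts:  # the single K=0 strategy was already returned
                logger.info("alternative enumeration exhausted after %d strategies", len(out))
                break
            deleted, outer = frozenset(), None
        else:
            solved = _build_and_solve_milp(
                model, env, target_id, candidates, config.K, f_min,
                config.big_M, config.mip_gap, cuts,
            )
            if solved is None:
                if not out:
                    raise NoStrategyError(
                        f"no strategy at K={config.K}, f_min={f_min:g}"
                    )
                logger.info("alternative enumeration exhausted after %d strategies", len(out))
                break
            deleted, outer, _gap = solved

        record = lp_record(deleted)
        if outer is not None and abs(record.target_flux_max - outer) > 1e-5 * max(1.0, abs(outer)):
            logger.warning(
                "MILP outer objective %.9g disagrees with LP verification %.9g "
                "for deletions %s (big-M artifact); trusting the LPs",
                outer, record.target_flux_max, sorted(deleted),
            )
        cuts.append(deleted)
        pruned = _prune_deletions(model, env, target_id, deleted, f_min,
                                  record.target_flux_max)
        if pruned != deleted:
            cuts.append(pruned)
            record = lp_record(pruned)
        if pruned in seen:
            continue
        seen.add(pruned)
        out.append(KnockoutStrategy(
            reactions=tuple(sorted(pruned)),
            growth=record.growth,
            target_flux_max=record.target_flux_max,
            target_flux_min=record.target_flux_min,
            yield_g_per_g=record.yield_g_per_g,
            gene_sets=_realize_gene_sets(model, pruned),
            solver_gap=None if outer is None else 0.0,
        ))

    out.sort(key=lambda s: (-s.target_flux_max, len(s.reactions), s.reactions))
    return out


def _realize_gene_sets(
    model: MetabolicModel, deleted: frozenset[str]
) -> tuple[frozenset[str], ...]:
    """Gene-level realization of a reaction deletion set, when one exists."""
    if not deleted:
        return ()
    try:
        sets = minimal_gene_knockouts(model, deleted)
    except ValueError:
        return ()
    return tuple(ks.genes for ks in sets)


def iterative_refine(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    config: OptKnockConfig,
    ban: set[str] | frozenset[str],
) -> KnockoutStrategy:
    """Re-run OptKnock with reactions removed from the candidate set.

    This is the refinement loop used when early solutions propose deletions
    one does not want to implement: ban them and re-optimize.  Banned ids not
    in the candidate set are warned about and ignored; banning the whole set
    is an error.
    """
    wt = solve_fba(model, env)
    if not wt.optimal:
        raise NoStrategyError(f"wild-type FBA is {wt.status}")
    f_min = config.resolve_f_min(wt.objective_value)
    if config.candidates is not None:
        candidates = sorted(config.candidates)
    else:
        candidates, _ = build_candidate_set(model, env, f_min)
    outside = set(ban) - set(candidates)
    if outside:
        logger.warning("banned reactions not in the candidate set are ignored: %s",
                       sorted(outside))
    remaining = [c for c in candidates if c not in ban]
    if not remaining:
        raise ValueError("candidate set is empty after applying the ban list")
    cfg = replace(config, candidates=tuple(remaining), ban=frozenset())
    strategy = solve_optknock(model, env, target_id, cfg)
    assert not (set(strategy.reactions) & set(ban))
    return strategy


def verify_strategy(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    strategy: KnockoutStrategy,
    substrate_exchange: str = "EX_glc_e",
    mw_target: float = MOLAR_MASS["2,3-butanediol"],
    mw_substrate: float = MOLAR_MASS["glucose"],
    envelope_points: int = 20,
) -> VerificationRecord:
    """Independent LP verification of a strategy's claims.

    Applies the knockouts, computes growth and the lexicographic max/min of
    the target flux at that growth, the g/g mass yield, and (optionally) the
    production envelope.  Discrepancies beyond 1e-6 relative against the
    strategy's stored predictions are flagged, as is infeasibility.
    """
    ko_model, _ = apply_knockouts(model, reactions=set(strategy.reactions))
    sol = solve_fba(ko_model, env)
    flags: list[str] = []
    if not sol.optimal:
        return VerificationRecord(
            reactions=strategy.reactions, growth=0.0, target_flux_max=0.0,
            target_flux_min=0.0, yield_g_per_g=0.0, envelope=None,
            flags=(f"infeasible after knockout ({sol.status})",),
        )
    growth = float(sol.objective_value)
    vmax = fix_and_optimize(ko_model, env, ko_model.objective_id, target_id, sense="max")
    vmin = fix_and_optimize(ko_model, env, ko_model.objective_id, target_id, sense="min")
    t_max = float(vmax.objective_value)
    t_min = float(vmin.objective_value)
    substrate_flux = vmax.fluxes.get(substrate_exchange, 0.0)
    if substrate_flux == 0.0:
        yld = 0.0
        if t_max > 1e-9:
            flags.append(f"no substrate uptake through {substrate_exchange}")
    else:
        yld = flux_to_mass_yield(t_max, substrate_flux, mw_target, mw_substrate).mass_yield
    envelope = None
    if envelope_points >= 2:
        envelope = production_envelope(ko_model, env, target_id, n_points=envelope_points)

    for label, stored, computed in (
        ("growth", strategy.growth, growth),
        ("target_flux_max", strategy.target_flux_max, t_max),
        ("target_flux_min", strategy.target_flux_min, t_min),
        ("yield", strategy.yield_g_per_g, yld),
    ):
        if stored is not None and np.isfinite(stored):
            if abs(stored - computed) > 1e-6 * max(1.0, abs(computed)):
                flags.append(
                    f"{label} mismatch: stored {stored:.9g} vs recomputed {computed:.9g}"
                )
    return VerificationRecord(
        reactions=strategy.reactions, growth=growth, target_flux_max=t_max,
        target_flux_min=t_min, yield_g_per_g=yld, envelope=envelope,
        flags=tuple(flags),
    )
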