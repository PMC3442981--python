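"""Synthetic models: the PYRCORE fixture, a seeded generator, and the oracle.

PYRCORE is a hand-solvable two-compartment fermentation network built around
the pyruvate branch point of budding yeast: glucose is taken up and split
into triose units; a lumped lower-glycolysis step produces pyruvate, NADH and
ATP; pyruvate feeds biomass, decarboxylation to acetaldehyde (and onward to
ethanol via ADH), and the acetoin -> 2,3-butanediol branch; the triose node
carries a glycerol overflow valve (GPD) that reoxidizes NADH; respiration
recycles NADH to ATP with a P/O ratio of 2.  Stoichiometry is lumped so that
every optimum of interest is a small rational number, while preserving the
redox logic (NADH supply and its competing sinks) that drives growth-coupled
2,3-butanediol production when ethanol formation is removed.

Acetoin deliberately has no transport or exchange reaction, so the
acetoin -> butanediol flux equality is forced and all hand solutions are
airtight.

:func:`make_random_model` composes the same balanced templates (substrate
chain with cofactor coupling, branch sinks, respiration-like recyclers,
maintenance) under a seeded RNG, so every generated model is mass-balanced
and growth-feasible by construction.  :func:`brute_force_design` is the
exhaustive knockout-design oracle used as ground truth for the OptKnock MILP.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .fba_core import EnvironmentSpec, apply_knockouts, fix_and_optimize, solve_fba
from .model_io import GPR_TRUE, MetabolicModel, Metabolite, Reaction, parse_gpr

logger = logging.getLogger("budstrain")

BIG = 1000.0


def _rxn(rid, stoich, lb=0.0, ub=BIG, gpr="", kind_tag=None, name=""):
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=parse_gpr(gpr) if gpr else GPR_TRUE,
        kind_tag=kind_tag,
        name=name or rid,
    )


def make_pyrcore() -> MetabolicModel:
    """The canonical 20-reaction, 2-compartment, 7-gene fermentation fixture."""
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("o2_e", "oxygen", "e"),
        Metabolite("etoh_e", "ethanol", "e"),
        Metabolite("glyc_e", "glycerol", "e"),
        Metabolite("bdo_e", "2,3-butanediol", "e"),
        Metabolite("co2_e", "carbon dioxide", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("tp_c", "triose phosphate", "c"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("acd_c", "acetaldehyde", "c"),
        Metabolite("actn_c", "acetoin", "c"),
        Metabolite("etoh_c", "ethanol", "c"),
        Metabolite("glyc_c", "glycerol", "c"),
        Metabolite("bdo_c", "2,3-butanediol", "c"),
        Metabolite("co2_c", "carbon dioxide", "c"),
        Metabolite("o2_c", "oxygen", "c"),
        Metabolite("nad_c", "NAD+", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("atp_c", "ATP", "c"),
        Metabolite("adp_c", "ADP", "c"),
        Metabolite("bio_c", "biomass", "c"),
    ]
    rxns = [
        _rxn("EX_glc_e", {"glc_e": -1}, lb=-10.0, ub=0.0, name="glucose exchange"),
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, name="glucose transport"),
        _rxn("GLY1", {"glc_c": -1, "tp_c": 2}, name="upper glycolysis (lumped)"),
        _rxn(
            "GLY2",
            {"tp_c": -1, "nad_c": -1, "adp_c": -2, "pyr_c": 1, "nadh_c": 1, "atp_c": 2},
            name="lower glycolysis (lumped)",
        ),
        _rxn(
            "GPD",
            {"tp_c": -1, "nadh_c": -1, "glyc_c": 1, "nad_c": 1},
            gpr="GPD1 or GPD2",
            name="glycerol branch (G3P dehydrogenase, lumped)",
        ),
        _rxn(
            "PDC",
            {"pyr_c": -1, "acd_c": 1, "co2_c": 1},
            gpr="PDC1",
            name="pyruvate decarboxylase",
        ),
        _rxn(
            "ACB",
            {"pyr_c": -1, "acd_c": -1, "actn_c": 1, "co2_c": 1},
            gpr="PDC1",
            name="acetoin condensation (PDC carboligase activity)",
        ),
        _rxn(
            "ADH",
            {"acd_c": -1, "nadh_c": -1, "etoh_c": 1, "nad_c": 1},
            gpr="ADH1 or ADH3 or ADH5",
            name="alcohol dehydrogenase (isozymes)",
        ),
        _rxn(
            "BDH",
            {"actn_c": -1, "nadh_c": -1, "bdo_c": 1, "nad_c": 1},
            gpr="BDH1",
            name="butanediol dehydrogenase",
        ),
        _rxn(
            "RESP",
            {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "nad_c": 1, "atp_c": 2},
            name="respiration (P/O = 2, lumped)",
        ),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, name="oxygen transport"),
        _rxn("EX_o2_e", {"o2_e": -1}, lb=-2.0, ub=0.0, name="oxygen exchange"),
        _rxn(
            "ATPM",
            {"atp_c": -1, "adp_c": 1},
            lb=1.0,
            kind_tag="maintenance",
            name="ATP maintenance",
        ),
        _rxn(
            "BIOMASS",
            {"pyr_c": -1, "atp_c": -3, "adp_c": 3, "bio_c": 1},
            kind_tag="biomass",
            name="biomass (lumped)",
        ),
        _rxn("EX_bio_c", {"bio_c": -1}, name="biomass drain"),
        _rxn("ETOHt", {"etoh_c": -1, "etoh_e": 1}, name="ethanol transport"),
        _rxn("EX_etoh_e", {"etoh_e": -1}, name="ethanol exchange"),
        _rxn("GLYCt", {"glyc_c": -1, "glyc_e": 1}, name="glycerol transport"),
        _rxn("EX_glyc_e", {"glyc_e": -1}, name="glycerol exchange"),
        _rxn("BDOt", {"bdo_c": -1, "bdo_e": 1}, name="butanediol transport"),
        _rxn("EX_bdo_e", {"bdo_e": -1}, name="butanediol exchange"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, name="CO2 transport"),
        _rxn("EX_co2_e", {"co2_e": -1}, name="CO2 exchange"),
    ]
    return MetabolicModel(
        id="PYRCORE",
        metabolites=mets,
        reactions=rxns,
        genes=frozenset(["ADH1", "ADH3", "ADH5", "GPD1", "GPD2", "PDC1", "BDH1"]),
        objective_id="BIOMASS",
    )


@dataclass(frozen=True)
class RandomModelSpec:
    """Parameters of the seeded random model generator.

    ``n_segments`` linear chain reactions between substrate and hub;
    ``n_cofactor_pairs`` redox couples (pair 0 is always the
    respiration-coupled NADH-like pair); ``n_branch_products`` secreted
    branch products drawing on the hub and reduced cofactors.
    """

    seed: int = 42
    n_segments: int = 3
    n_cofactor_pairs: int = 1
    n_branch_products: int = 3
    bound_magnitude: float = BIG

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_cofactor_pairs < 1:
            raise ValueError("n_cofactor_pairs must be >= 1")
        if self.n_branch_products < 1:
            raise ValueError("n_branch_products must be >= 1")


def make_random_model(spec: RandomModelSpec) -> MetabolicModel:
    """Generate a PYRCORE-like model from balanced templates, seeded.

    The topology is substrate chain -> hub, branch products with cofactor
    coupling, one oxidase ("respiration") per cofactor pair, maintenance and
    a biomass drain.  Every reaction conserves each cofactor couple, so the
    model is stoichiometrically consistent and growth-feasible at the default
    environment by construction.  Identical seeds give identical models.
    """
    rng = np.random.default_rng(spec.seed)
    B = spec.bound_magnitude
    mets: list[Metabolite] = [
        Metabolite("glc_e", "substrate", "e"),
        Metabolite("o2_e", "oxygen", "e"),
        Metabolite("o2_c", "oxygen", "c"),
        Metabolite("atp_c", "ATP", "c"),
        Metabolite("adp_c", "ADP", "c"),
        Metabolite("bio_c", "biomass", "c"),
    ]
    for k in range(spec.n_cofactor_pairs):
        mets.append(Metabolite(f"red{k}_c", f"cofactor {k} (oxidized)", "c"))
        mets.append(Metabolite(f"redh{k}_c", f"cofactor {k} (reduced)", "c"))

    genes: set[str] = set()
    rxns: list[Reaction] = []

    def gene_pool(prefix: str, n: int) -> list[str]:
        names = [f"{prefix}{i + 1}" for i in range(n)]
        genes.update(names)
        return names

    def random_gpr(prefix: str) -> str:
        kind = rng.integers(0, 3)
        if kind == 0:  # single gene
            return gene_pool(prefix, 1)[0]
        if kind == 1:  # isozymes (OR)
            return " or ".join(gene_pool(prefix, int(rng.integers(2, 4))))
        return " and ".join(gene_pool(prefix, int(rng.integers(2, 4))))  # complex

    rxns.append(_rxn("EX_glc_e", {"glc_e": -1}, lb=-10.0, ub=0.0))
    rxns.append(_rxn("EX_o2_e", {"o2_e": -1}, lb=-2.0, ub=0.0))
    rxns.append(_rxn("O2t", {"o2_e": -1, "o2_c": 1}))

    # substrate chain: glc_e -> x0 -> ... -> hub; the final step is always the
    # ATP/NADH-yielding payoff step so the model can meet maintenance
    mets.append(Metabolite("x0_c", "chain intermediate 0", "c"))
    rxns.append(_rxn("CHAINt", {"glc_e": -1, "x0_c": 1}))
    for i in range(spec.n_segments):
        src = f"x{i}_c"
        dst = f"x{i + 1}_c" if i < spec.n_segments - 1 else "hub_c"
        if dst != "hub_c":
            mets.append(Metabolite(dst, f"chain intermediate {i + 1}", "c"))
        stoich = {src: -1.0, dst: 1.0}
        if i == spec.n_segments - 1:
            # payoff step: 2 ATP plus one reduced pair-0 cofactor per unit
            stoich.update({"red0_c": -1.0, "redh0_c": 1.0, "adp_c": -2.0, "atp_c": 2.0})
        elif rng.random() < 0.5:
            # optional extra reduction step on a random cofactor pair
            k = int(rng.integers(0, spec.n_cofactor_pairs))
            stoich.update({f"red{k}_c": -1.0, f"redh{k}_c": 1.0})
        rxns.append(_rxn(f"CHAIN{i}", stoich, gpr=random_gpr(f"C{i}G")))
    mets.append(Metabolite("hub_c", "hub metabolite", "c"))

    # a randomly chosen chain step gets an isozyme duplicate, so that step is
    # not individually essential and enters the candidate set
    dup = int(rng.integers(0, spec.n_segments))
    dup_rxn = next(r for r in rxns if r.id == f"CHAIN{dup}")
    rxns.append(_rxn(f"CHAIN{dup}b", dict(dup_rxn.stoichiometry), gpr=random_gpr(f"C{dup}H")))

    # branch products: hub (+ reduced cofactor) -> product, exported.  Branch 0
    # always draws on the respiration-coupled pair 0 so the design problem
    # (force flux into it by removing competing NADH sinks) is never vacuous.
    for b in range(spec.n_branch_products):
        prod_c, prod_e = f"p{b}_c", f"p{b}_e"
        mets.append(Metabolite(prod_c, f"branch product {b}", "c"))
        mets.append(Metabolite(prod_e, f"branch product {b}", "e"))
        k = 0 if b == 0 else int(rng.integers(0, spec.n_cofactor_pairs))
        coupling = float(rng.integers(1, 3))
        stoich = {
            "hub_c": -1.0,
            f"redh{k}_c": -coupling,
            f"red{k}_c": coupling,
            prod_c: 1.0,
        }
        rxns.append(_rxn(f"BRANCH{b}", stoich, gpr=random_gpr(f"B{b}G")))
        rxns.append(_rxn(f"P{b}t", {prod_c: -1.0, prod_e: 1.0}))
        rxns.append(_rxn(f"EX_p{b}_e", {prod_e: -1.0}))

    # redox-free overflow valve: hub -> waste, exported
    mets.append(Metabolite("w_c", "waste product", "c"))
    mets.append(Metabolite("w_e", "waste product", "e"))
    rxns.append(_rxn("WASTE", {"hub_c": -1.0, "w_c": 1.0}, gpr=random_gpr("WG")))
    rxns.append(_rxn("Wt", {"w_c": -1.0, "w_e": 1.0}))
    rxns.append(_rxn("EX_w_e", {"w_e": -1.0}))

    # one oxygen-dependent oxidase per cofactor pair; pair 0 yields ATP
    for k in range(spec.n_cofactor_pairs):
        stoich = {f"redh{k}_c": -1.0, "o2_c": -0.5, f"red{k}_c": 1.0}
        if k == 0:
            stoich.update({"adp_c": -2.0, "atp_c": 2.0})
        rxns.append(_rxn(f"OX{k}", stoich))

    rxns.append(_rxn("ATPM", {"atp_c": -1, "adp_c": 1}, lb=1.0, kind_tag="maintenance"))
    biomass_atp = float(rng.integers(2, 5))
    rxns.append(
        _rxn(
            "BIOMASS",
            {"hub_c": -1.0, "atp_c": -biomass_atp, "adp_c": biomass_atp, "bio_c": 1.0},
            kind_tag="biomass",
        )
    )
    rxns.append(_rxn("EX_bio_c", {"bio_c": -1}))

    if B != BIG:
        from dataclasses import replace

        rxns = [
            replace(
                r,
                lower_bound=-B if r.lower_bound == -BIG else r.lower_bound,
                upper_bound=B if r.upper_bound == BIG else r.upper_bound,
            )
            for r in rxns
        ]
    model = MetabolicModel(
        id=f"RANDOM-{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        genes=frozenset(genes),
        objective_id="BIOMASS",
    )
    # generator contract: growth-feasible at the default environment
    from .fba_core import default_environment

    sol = solve_fba(model, default_environment())
    if not sol.optimal or sol.objective_value <= 0:  # pragma: no cover - contract
        raise RuntimeError(f"generated model {model.id} is not growth-feasible")
    return model


#: guard on the oracle's subset enumeration
MAX_ORACLE_SUBSETS = 50_000


@dataclass(frozen=True)
class OracleResult:
    deleted: tuple[str, ...]
    growth: float
    target_flux: float  # lexicographic max at maximal growth


def brute_force_design(
    model: MetabolicModel,
    env: EnvironmentSpec,
    target_id: str,
    K: int,
    candidates: list[str],
    f_min: float,
) -> OracleResult:
    """Exhaustive knockout-design oracle.

    Enumerates every candidate subset of size <= K, evaluates each by
    lexicographic FBA (growth first, then max target flux at that growth),
    and returns the viable subset with maximal target flux; ties break to
    fewer knockouts, then lexicographic ids.  Independent of the MILP path.
    """
    import math

    n_subsets = sum(math.comb(len(candidates), k) for k in range(K + 1))
    if n_subsets > MAX_ORACLE_SUBSETS:
        raise ValueError(
            f"{n_subsets} subsets exceed the enumeration guard "
            f"({MAX_ORACLE_SUBSETS}); reduce K or the candidate set"
        )
    best: OracleResult | None = None
    for k in range(K + 1):
        for combo in itertools.combinations(sorted(candidates), k):
            ko_model, _ = apply_knockouts(model, reactions=set(combo))
            sol = solve_fba(ko_model, env)
            if not sol.optimal or sol.objective_value < f_min - 1e-9:
                continue
            lexi = fix_and_optimize(ko_model, env, ko_model.objective_id, target_id, "max")
            cand = OracleResult(
                deleted=combo,
                growth=float(sol.objective_value),
                target_flux=float(lexi.objective_value),
            )
            if (
                best is None
                or cand.target_flux > best.target_flux + 1e-9
                or (
                    abs(cand.target_flux - best.target_flux) <= 1e-9
                    and (len(cand.deleted), cand.deleted) < (len(best.deleted), best.deleted)
                )
            ):
                best = cand
    if best is None:
        raise RuntimeError("no feasible subset (wild type itself is below f_min)")
    return best
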