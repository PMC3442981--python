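"""Constraint-based metabolic models: containers, GPR logic, SBML/JSON I/O.

A :class:`MetabolicModel` is the in-memory representation used throughout the
package: a list of metabolites, a list of bounded reactions with
gene-protein-reaction (GPR) boolean rules, and a declared objective reaction
(the biomass equation).  Metabolite ids follow the ``<species>_<compartment>``
convention of the iMM904-era model dialect (``glc_e``, ``pyr_c``); the
compartment suffix is what makes transport detection purely syntactic.

Two serialization formats are supported:

* SBML — Level 3 with the FBC v2 extension, and the legacy Level 2 dialect
  that stores bounds in kinetic-law parameters and GPRs in ``GENE_ASSOCIATION``
  notes (the dialect genome-scale yeast models of the iMM904 generation were
  distributed in).  The dialect is auto-detected on read.
* a native JSON schema, versioned ``budstrain-model/1``.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("budstrain")

REACTION_KINDS = ("exchange", "transport", "internal", "biomass", "maintenance")

#: default magnitude used for effectively unbounded flux directions
DEFAULT_BOUND = 1000.0


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

class GPRParseError(ValueError):
    """Raised for malformed GPR rule text; carries the offending position."""

    def __init__(self, message: str, position: int, text: str):
        super().__init__(f"{message} at position {position} in GPR rule {text!r}")
        self.position = position
        self.text = text


@dataclass(frozen=True)
class GPRExpression:
    """Boolean expression tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"true"`` (the empty,
    always-on rule).  Trees are immutable; evaluation assigns ``False`` to
    deleted genes and ``True`` to all others.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def __post_init__(self):
        if self.op not in ("gene", "and", "or", "true"):
            raise ValueError(f"unknown GPR node op {self.op!r}")
        if self.op == "gene" and not self.gene:
            raise ValueError("gene node requires a gene id")
        if self.op in ("and", "or") and len(self.children) < 2:
            raise ValueError(f"{self.op!r} node requires >= 2 children")

    @property
    def is_always_on(self) -> bool:
        return self.op == "true"

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, deleted_genes: set[str] | frozenset[str]) -> bool:
        """True iff the reaction remains catalysable with ``deleted_genes`` absent."""
        if self.op == "true":
            return True
        if self.op == "gene":
            return self.gene not in deleted_genes
        if self.op == "and":
            return all(c.evaluate(deleted_genes) for c in self.children)
        return any(c.evaluate(deleted_genes) for c in self.children)

    def dnf(self) -> list[frozenset[str]]:
        """Disjunctive normal form as a list of gene conjunctions.

        Each returned frozenset is one way of realizing the reaction (an
        isozyme alternative); redundant supersets are pruned.  The always-on
        expression returns a single empty conjunct.
        """
        if self.op == "true":
            return [frozenset()]
        if self.op == "gene":
            return [frozenset([self.gene])]
        if self.op == "or":
            terms: list[frozenset[str]] = []
            for c in self.children:
                terms.extend(c.dnf())
        else:  # and: cross product of children's DNFs
            terms = [frozenset()]
            for c in self.children:
                terms = [a | b for a in terms for b in c.dnf()]
        # prune non-minimal conjuncts for a canonical result
        terms = sorted(set(terms), key=lambda s: (len(s), sorted(s)))
        minimal: list[frozenset[str]] = []
        for t in terms:
            if not any(m <= t for m in minimal):
                minimal.append(t)
        return minimal

    def to_string(self) -> str:
        if self.op == "true":
            return ""
        if self.op == "gene":
            return self.gene
        joiner = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or"):
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


GPR_TRUE = GPRExpression(op="true")

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.-]+)")


def parse_gpr(rule_text: str) -> GPRExpression:
    """Parse a GPR rule string into an expression tree.

    Grammar: case-insensitive ``and`` / ``or`` connectives, parentheses, gene
    ids matching ``[A-Za-z0-9_.-]+``.  Empty/whitespace text yields the
    always-on expression.  Raises :class:`GPRParseError` with the character
    position on malformed input.
    """
    text = rule_text or ""
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise GPRParseError("unexpected character", pos + (len(text[pos:]) - len(stripped)), text)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    if not tokens:
        return GPR_TRUE

    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def take() -> tuple[str, int]:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_or() -> GPRExpression:
        terms = [parse_and()]
        while peek() is not None and peek()[0].lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRExpression(op="or", children=tuple(terms))

    def parse_and() -> GPRExpression:
        factors = [parse_factor()]
        while peek() is not None and peek()[0].lower() == "and":
            take()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else GPRExpression(op="and", children=tuple(factors))

    def parse_factor() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise GPRParseError("dangling connective", len(text), text)
        word, at = take()
        if word == "(":
            inner = parse_or()
            nxt = peek()
            if nxt is None or nxt[0] != ")":
                raise GPRParseError("unclosed parenthesis", at, text)
            take()
            return inner
        if word == ")":
            raise GPRParseError("unexpected ')'", at, text)
        if word.lower() in ("and", "or"):
            raise GPRParseError("dangling connective", at, text)
        return GPRExpression(op="gene", gene=word)

    expr = parse_or()
    if idx != len(tokens):
        raise GPRParseError("unexpected token", tokens[idx][1], text)
    return expr


def evaluate_gpr(expr: GPRExpression, deleted_genes: set[str] | frozenset[str]) -> bool:
    """Standard boolean semantics with deleted genes assigned false."""
    return expr.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    @property
    def base_species(self) -> str:
        """Compartment-stripped identity (``glc_e`` -> ``glc``)."""
        if "_" in self.id and self.id.rsplit("_", 1)[1] == self.compartment:
            return self.id.rsplit("_", 1)[0]
        return self.id


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = GPR_TRUE
    name: str = ""
    #: explicit tag for pseudo-reactions; None means kind is inferred
    kind_tag: str | None = None

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds upper {self.upper_bound}"
            )
        if self.kind_tag not in (None, "biomass", "maintenance"):
            raise ValueError(f"reaction {self.id}: invalid kind tag {self.kind_tag!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class ModelValidationError(ValueError):
    pass


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, bounded reactions, GPRs, objective."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: frozenset[str]
    objective_id: str

    def __post_init__(self):
        self.validate()

    # -- lookups ------------------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rxn_id]]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r} in model {self.id!r}") from None

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError(f"model {self.id}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError(f"model {self.id}: duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id} references undeclared metabolites {sorted(missing)}"
                )
            extra = r.gpr.genes() - self.genes
            if extra:
                raise ModelValidationError(
                    f"reaction {r.id} GPR uses genes absent from the model gene set: {sorted(extra)}"
                )
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model {self.id}"
            )

    def stoichiometric_matrix(self) -> sp.csr_matrix:
        """S (metabolites x reactions), negative coefficient = consumed."""
        midx = self.metabolite_index
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                rows.append(midx[met_id])
                cols.append(j)
                vals.append(float(coef))
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=self.genes,
            objective_id=self.objective_id,
        )

    def with_bounds(self, overrides: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Derived copy with (lb, ub) replaced for the listed reaction ids."""
        unknown = set(overrides) - set(self.reaction_index)
        if unknown:
            raise KeyError(f"bound overrides for unknown reactions {sorted(unknown)}")
        new_reactions = []
        for r in self.reactions:
            if r.id in overrides:
                lo, hi = overrides[r.id]
                r = replace(r, lower_bound=float(lo), upper_bound=float(hi))
            new_reactions.append(r)
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=new_reactions,
            genes=self.genes,
            objective_id=self.objective_id,
        )


# ---------------------------------------------------------------------------
# Reaction classification
# ---------------------------------------------------------------------------

def classify_reaction(model: MetabolicModel, reaction_id: str) -> str:
    """Classify a reaction as exchange/transport/internal/biomass/maintenance.

    Exchange: touches exactly one metabolite (a boundary reaction).
    Transport: spans >= 2 compartments and some base species appears in more
    than one of them.  Biomass and maintenance are explicit tags.
    """
    rxn = model.reaction(reaction_id)
    if rxn.kind_tag is not None:
        return rxn.kind_tag
    if reaction_id == model.objective_id:
        return "biomass"
    if len(rxn.stoichiometry) == 1:
        return "exchange"
    mets = [model.metabolite(mid) for mid in rxn.stoichiometry]
    compartments = {m.compartment for m in mets}
    if len(compartments) >= 2:
        by_species: dict[str, set[str]] = {}
        for m in mets:
            by_species.setdefault(m.base_species, set()).add(m.compartment)
        if any(len(comps) > 1 for comps in by_species.values()):
            return "transport"
    return "internal"


def classify_all(model: MetabolicModel) -> dict[str, str]:
    return {r.id: classify_reaction(model, r.id) for r in model.reactions}


# ---------------------------------------------------------------------------
# Minimal gene knockouts (reaction set -> gene sets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneKnockoutSet:
    """One minimal gene deletion set realizing a reaction knockout, with the
    collateral damage it causes elsewhere in the model."""

    genes: frozenset[str]
    side_effects: tuple[str, ...]  # other reactions also rendered inactive


class NotGeneDisableableError(ValueError):
    pass


#: above this many involved genes, fall back from exhaustive enumeration to a
#: set-cover integer program (which then reports minimum-cardinality sets)
_EXHAUSTIVE_GENE_LIMIT = 12


def minimal_gene_knockouts(
    model: MetabolicModel, reactions_to_disable: set[str] | frozenset[str]
) -> list[GeneKnockoutSet]:
    """Minimal gene sets whose deletion disables every listed reaction.

    Computed as minimal hitting sets over the union of the target reactions'
    DNF conjuncts.  With <= 12 involved genes all inclusion-minimal sets are
    found by exhaustive subset enumeration; for larger instances a set-cover
    integer program with integer cuts returns every minimum-cardinality set.
    Results are ordered by size then lexicographically.
    """
    targets = sorted(reactions_to_disable)
    if not targets:
        return [GeneKnockoutSet(genes=frozenset(), side_effects=())]
    conjuncts: list[frozenset[str]] = []
    for rid in targets:
        rxn = model.reaction(rid)
        if rxn.gpr.is_always_on:
            raise NotGeneDisableableError(
                f"reaction {rid} has an empty (always-on) GPR and is not gene-disableable"
            )
        conjuncts.extend(rxn.gpr.dnf())
    involved = sorted(set().union(*conjuncts))

    if len(involved) <= _EXHAUSTIVE_GENE_LIMIT:
        hitting_sets = _minimal_hitting_sets_exhaustive(conjuncts, involved)
    else:  # pragma: no cover - exercised only on large GPR systems
        hitting_sets = _minimum_hitting_sets_milp(conjuncts, involved)

    target_set = set(targets)
    out = []
    for genes in hitting_sets:
        side = tuple(
            r.id
            for r in model.reactions
            if r.id not in target_set
            and not r.gpr.is_always_on
            and not r.gpr.evaluate(genes)
        )
        out.append(GeneKnockoutSet(genes=genes, side_effects=side))
    out.sort(key=lambda ks: (len(ks.genes), sorted(ks.genes)))
    return out


def _minimal_hitting_sets_exhaustive(
    conjuncts: list[frozenset[str]], involved: list[str]
) -> list[frozenset[str]]:
    found: list[frozenset[str]] = []
    for size in range(0, len(involved) + 1):
        for combo in itertools.combinations(involved, size):
            cand = frozenset(combo)
            if any(prev <= cand for prev in found):
                continue
            if all(cand & conj for conj in conjuncts):
                found.append(cand)
    return found


def _minimum_hitting_sets_milp(
    conjuncts: list[frozenset[str]], involved: list[str]
) -> list[frozenset[str]]:  # pragma: no cover - large instances only
    from scipy.optimize import LinearConstraint, milp

    gidx = {g: i for i, g in enumerate(involved)}
    n = len(involved)
    rows = []
    for conj in set(conjuncts):
        row = np.zeros(n)
        for g in conj:
            row[gidx[g]] = 1.0
        rows.append(row)
    cover = LinearConstraint(np.array(rows), lb=1.0, ub=np.inf)
    cuts: list[np.ndarray] = []
    best_size = None
    found: list[frozenset[str]] = []
    while True:
        constraints = [cover]
        if cuts:
            constraints.append(LinearConstraint(np.array(cuts), lb=-np.inf, ub=[c.sum() - 1 for c in cuts]))
        res = milp(
            c=np.ones(n), constraints=constraints, integrality=np.ones(n), bounds=(0, 1)
        )
        if not res.success:
            break
        size = int(round(res.fun))
        if best_size is None:
            best_size = size
        if size > best_size:
            break
        sel = frozenset(involved[i] for i in range(n) if res.x[i] > 0.5)
        found.append(sel)
        cut = np.zeros(n)
        for g in sel:
            cut[gidx[g]] = 1.0
        cuts.append(cut)
    return found


# ---------------------------------------------------------------------------
# Native JSON schema (budstrain-model/1)
# ---------------------------------------------------------------------------

JSON_SCHEMA_VERSION = "budstrain-model/1"


class SchemaError(ValueError):
    """Schema violation in a native JSON model document; message carries a
    JSON-pointer-style path to the offending element."""


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema": JSON_SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "kind_tag": r.kind_tag,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_id,
    }


def model_from_dict(doc: dict) -> MetabolicModel:
    def need(container, key, where, typ=None):
        if not isinstance(container, dict) or key not in container:
            raise SchemaError(f"missing key at {where}/{key}")
        val = container[key]
        if typ is not None and not isinstance(val, typ):
            raise SchemaError(f"wrong type at {where}/{key}: expected {typ.__name__}")
        return val

    if need(doc, "schema", "", str) != JSON_SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema at /schema: {doc.get('schema')!r}")
    mets = [
        Metabolite(
            id=need(m, "id", f"/metabolites/{i}", str),
            name=m.get("name", ""),
            compartment=need(m, "compartment", f"/metabolites/{i}", str),
        )
        for i, m in enumerate(need(doc, "metabolites", "", list))
    ]
    rxns = []
    for i, r in enumerate(need(doc, "reactions", "", list)):
        where = f"/reactions/{i}"
        try:
            gpr = parse_gpr(need(r, "gpr", where, str))
        except GPRParseError as exc:
            raise SchemaError(f"unparseable GPR at {where}/gpr: {exc}") from exc
        rxns.append(
            Reaction(
                id=need(r, "id", where, str),
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in need(r, "stoichiometry", where, dict).items()},
                lower_bound=float(need(r, "lower_bound", where)),
                upper_bound=float(need(r, "upper_bound", where)),
                gpr=gpr,
                kind_tag=r.get("kind_tag"),
            )
        )
    return MetabolicModel(
        id=need(doc, "id", "", str),
        metabolites=mets,
        reactions=rxns,
        genes=frozenset(need(doc, "genes", "", list)),
        objective_id=need(doc, "objective", "", str),
    )


def write_model_json(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    return model_from_dict(doc)


def model_json_string(model: MetabolicModel) -> str:
    return json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

class SBMLError(ValueError):
    pass


_KIND_NOTE = re.compile(r"BUDSTRAIN_KIND:\s*(\w+)")
_GA_NOTE = re.compile(r"GENE[ _]ASSOCIATION:\s*([^<\n]*)")


def _sid(raw: str) -> str:
    """Sanitize into a valid SBML SId (prefix to avoid a leading digit)."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "x_" + s
    return s


def write_sbml(model: MetabolicModel, path, dialect: str = "fbc") -> None:
    """Serialize to SBML.

    ``dialect="fbc"`` writes Level 3 + FBC v2 (bounds as parameters, GPRs as
    gene-product associations); ``dialect="cobra-notes"`` writes Level 2 with
    kinetic-law bound parameters and ``GENE_ASSOCIATION`` notes, the legacy
    encoding used by iMM904-generation model distributions.
    """
    import libsbml

    if dialect == "fbc":
        _write_sbml_fbc(model, path, libsbml)
    elif dialect == "cobra-notes":
        _write_sbml_notes(model, path, libsbml)
    else:
        raise ValueError(f"unknown SBML dialect {dialect!r}")


def _reaction_notes(rxn: Reaction, html: bool) -> str | None:
    lines = []
    if not rxn.gpr.is_always_on:
        lines.append(f"GENE_ASSOCIATION: {rxn.gpr.to_string()}")
    if rxn.kind_tag is not None:
        lines.append(f"BUDSTRAIN_KIND: {rxn.kind_tag}")
    if not lines:
        return None
    body = "".join(f"<p>{ln}</p>" for ln in lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _split_stoich(rxn: Reaction):
    reactants = {m: -c for m, c in rxn.stoichiometry.items() if c < 0}
    products = {m: c for m, c in rxn.stoichiometry.items() if c > 0}
    return reactants, products


def _write_sbml_fbc(model: MetabolicModel, path, libsbml) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    sbml_model.setName(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for m in model.metabolites:
        sp_ = sbml_model.createSpecies()
        sp_.setId(_sid(m.id))
        sp_.setName(m.name or m.id)
        sp_.setCompartment(m.compartment)
        sp_.setHasOnlySubstanceUnits(False)
        sp_.setBoundaryCondition(False)
        sp_.setConstant(False)

    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid(g))
        gp.setLabel(g)

    # unique flux-bound parameters per reaction
    for r in model.reactions:
        for suffix, value in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            par = sbml_model.createParameter()
            par.setId(_sid(f"bnd_{r.id}_{suffix}"))
            par.setValue(float(value))
            par.setConstant(True)

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(_sid(r.id))
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        reactants, products = _split_stoich(r)
        for met_id, coef in sorted(reactants.items()):
            ref = rx.createReactant()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        for met_id, coef in sorted(products.items()):
            ref = rx.createProduct()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_sid(f"bnd_{r.id}_lb"))
        rplug.setUpperFluxBound(_sid(f"bnd_{r.id}_ub"))
        if not r.gpr.is_always_on:
            assoc = rplug.createGeneProductAssociation()
            assoc.setAssociation(_gpr_to_fbc_string(r.gpr), True, False)
        notes = _reaction_notes(replace(r, gpr=GPR_TRUE), html=True)
        if notes:
            rx.setNotes(notes)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(_sid(model.objective_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLError(f"could not write SBML to {path}")


def _gpr_to_fbc_string(expr: GPRExpression) -> str:
    if expr.op == "gene":
        return _sid(expr.gene)
    joiner = f" {expr.op} "
    parts = []
    for c in expr.children:
        s = _gpr_to_fbc_string(c)
        if c.op in ("and", "or"):
            s = f"({s})"
        parts.append(s)
    return joiner.join(parts)


def _write_sbml_notes(model: MetabolicModel, path, libsbml) -> None:
    doc = libsbml.SBMLDocument(2, 4)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    sbml_model.setName(model.id)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)

    for m in model.metabolites:
        sp_ = sbml_model.createSpecies()
        sp_.setId(_sid(m.id))
        sp_.setName(m.name or m.id)
        sp_.setCompartment(m.compartment)
        sp_.setBoundaryCondition(False)

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(_sid(r.id))
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        reactants, products = _split_stoich(r)
        for met_id, coef in sorted(reactants.items()):
            ref = rx.createReactant()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(float(coef))
        for met_id, coef in sorted(products.items()):
            ref = rx.createProduct()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(float(coef))
        kl = rx.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", r.lower_bound),
            ("UPPER_BOUND", r.upper_bound),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT", 1.0 if r.id == model.objective_id else 0.0),
        ):
            par = kl.createParameter()
            par.setId(pid)
            par.setValue(float(value))
        notes = _reaction_notes(r, html=True)
        if notes:
            rx.setNotes(notes)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLError(f"could not write SBML to {path}")


def read_sbml(path) -> MetabolicModel:
    """Read an SBML model, auto-detecting the FBC or legacy-notes dialect.

    Raises :class:`SBMLError` naming the line for XML parse failures, the
    reaction for missing bounds, and the rule text for unparseable GPRs.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLError(f"{path}: document contains no model")

    fbc = sbml_model.getPlugin("fbc")
    use_fbc = fbc is not None and doc.getLevel() >= 3
    dialect = "fbc" if use_fbc else "cobra-notes"
    logger.info("reading SBML %s (detected dialect: %s)", path, dialect)

    label_by_sid: dict[str, str] = {}
    if use_fbc:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label_by_sid[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        if s.getBoundaryCondition():
            continue
        metabolites.append(
            Metabolite(id=s.getId(), name=s.getName() or "", compartment=s.getCompartment())
        )

    boundary_ids = {
        sbml_model.getSpecies(i).getId()
        for i in range(sbml_model.getNumSpecies())
        if sbml_model.getSpecies(i).getBoundaryCondition()
    }

    genes: set[str] = set()
    reactions = []
    objective_id = None
    if use_fbc:
        active = fbc.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() in boundary_ids:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() in boundary_ids:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        notes = rx.getNotesString() if rx.isSetNotes() else ""
        kind_tag = None
        m = _KIND_NOTE.search(notes)
        if m and m.group(1) in ("biomass", "maintenance"):
            kind_tag = m.group(1)

        gpr = GPR_TRUE
        lb = ub = None
        if use_fbc:
            rplug = rx.getPlugin("fbc")
            for attr, setter in (("getLowerFluxBound", "lb"), ("getUpperFluxBound", "ub")):
                pid = getattr(rplug, attr)()
                par = sbml_model.getParameter(pid) if pid else None
                if par is not None and par.isSetValue():
                    if setter == "lb":
                        lb = par.getValue()
                    else:
                        ub = par.getValue()
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _fbc_association_to_gpr(gpa.getAssociation(), label_by_sid)
        else:
            kl = rx.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    par = kl.getParameter(j)
                    if par.getId() == "LOWER_BOUND":
                        lb = par.getValue()
                    elif par.getId() == "UPPER_BOUND":
                        ub = par.getValue()
                    elif par.getId() == "OBJECTIVE_COEFFICIENT" and par.getValue() != 0:
                        objective_id = rid
            m = _GA_NOTE.search(notes)
            if m:
                text = m.group(1).strip()
                if text:
                    try:
                        gpr = parse_gpr(text)
                    except GPRParseError as exc:
                        raise SBMLError(
                            f"reaction {rid}: unparseable GPR rule {text!r}: {exc}"
                        ) from exc
        if lb is None or ub is None:
            raise SBMLError(
                f"reaction {rid}: no flux bounds found (neither FBC bound parameters "
                f"nor kinetic-law LOWER_BOUND/UPPER_BOUND)"
            )
        if math.isinf(lb):
            lb = -DEFAULT_BOUND
        if math.isinf(ub):
            ub = DEFAULT_BOUND
        genes |= gpr.genes()
        reactions.append(
            Reaction(
                id=rid,
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                kind_tag=kind_tag,
            )
        )

    if objective_id is None:
        raise SBMLError(f"{path}: no objective reaction declared")

    model = MetabolicModel(
        id=sbml_model.getName() or sbml_model.getId(),
        metabolites=metabolites,
        reactions=reactions,
        genes=frozenset(genes),
        objective_id=objective_id,
    )
    logger.info(
        "read model %s: %d genes, %d reactions, %d metabolites",
        model.id, len(model.genes), len(model.reactions), len(model.metabolites),
    )
    return model


def _fbc_association_to_gpr(assoc, label_by_sid: dict[str, str]) -> GPRExpression:
    import libsbml

    if assoc is None:
        return GPR_TRUE
    if isinstance(assoc, libsbml.GeneProductRef):
        sid = assoc.getGeneProduct()
        return GPRExpression(op="gene", gene=label_by_sid.get(sid, sid))
    if isinstance(assoc, libsbml.FbcAnd):
        children = tuple(
            _fbc_association_to_gpr(assoc.getAssociation(i), label_by_sid)
            for i in range(assoc.getNumAssociations())
        )
        return children[0] if len(children) == 1 else GPRExpression(op="and", children=children)
    if isinstance(assoc, libsbml.FbcOr):
        children = tuple(
            _fbc_association_to_gpr(assoc.getAssociation(i), label_by_sid)
            for i in range(assoc.getNumAssociations())
        )
        return children[0] if len(children) == 1 else GPRExpression(op="or", children=children)
    raise SBMLError(f"unsupported gene association element {type(assoc).__name__}")
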