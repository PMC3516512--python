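"""Core domain types: compounds, reactions, stoichiometric signaling models.

A signaling network is encoded the COBRA way: a stoichiometric matrix S
(one row per chemical compound, one column per reaction), flux bounds per
reaction, and a Boolean gene-reaction association per reaction.  Unlike
metabolic models, compounds here are mostly proteins (receptors, kinases,
phosphatases, complexes) and "fluxes" are signal propagation rates in
arbitrary units.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .gpr import GPR_EMPTY, GprTree

__all__ = [
    "Compound",
    "Reaction",
    "Model",
    "CallMap",
    "COMPARTMENTS",
    "ROLES",
    "RCLASSES",
    "UNBOUNDED",
    "genes_of",
    "reactions_for_genes",
    "validate_model",
]

COMPARTMENTS = ("e", "c", "n", "v")
ROLES = ("receptor", "kinase", "phosphatase", "protein", "ligand", "metabolite", "complex")
RCLASSES = ("core", "transport", "binding", "exchange", "demand", "sink")

#: Conventional finite stand-in for an unconstrained flux bound.
UNBOUNDED = 1000.0

_COMPARTMENT_RE = re.compile(r"\[([a-z])\]$")


def compartment_of(compound_id: str) -> str | None:
    """Extract the bracket-suffix compartment from a compound id, if any."""
    m = _COMPARTMENT_RE.search(compound_id)
    return m.group(1) if m else None


@dataclass
class Compound:
    """A chemical compound (protein, ligand, metabolite or complex)."""

    id: str
    name: str = ""
    compartment: str = "c"
    role: str = "protein"


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a GPR rule.

    ``stoichiometry`` maps compound id to signed coefficient (negative =
    consumed, positive = produced).  ``rclass`` distinguishes core network
    conversions from boundary bookkeeping (exchange / demand / sink) and
    the ligand-receptor binding reactions used to stimulate inputs.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = UNBOUNDED
    gpr: GprTree = GPR_EMPTY
    rclass: str = "core"

    @property
    def reversible(self) -> bool:
        return self.lb < 0.0

    @property
    def is_boundary(self) -> bool:
        return self.rclass in ("exchange", "demand", "sink")

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lb, self.ub,
                        self.gpr, self.rclass)


#: Map gene id -> present (True) / absent (False).  Genes not listed take
#: the caller-supplied default (present, unless configured otherwise).
CallMap = Mapping[str, bool]


class Model:
    """An ordered collection of compounds and reactions plus a gene index."""

    def __init__(self, model_id: str = "model",
                 compounds: Iterable[Compound] = (),
                 reactions: Iterable[Reaction] = (),
                 gene_index: Mapping[str, dict] | None = None):
        self.id = model_id
        self.compounds: dict[str, Compound] = {}
        self.reactions: dict[str, Reaction] = {}
        self.gene_index: dict[str, dict] = dict(gene_index or {})
        for c in compounds:
            self.add_compound(c)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -------------------------------------------------
    def add_compound(self, compound: Compound) -> None:
        if compound.id in self.compounds:
            raise ValueError(f"duplicate compound id {compound.id!r}")
        self.compounds[compound.id] = compound

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reactions:
            raise ValueError(f"duplicate reaction id {reaction.id!r}")
        self.reactions[reaction.id] = reaction

    def copy(self) -> "Model":
        m = Model(self.id)
        m.compounds = {cid: _copy.copy(c) for cid, c in self.compounds.items()}
        m.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        m.gene_index = _copy.deepcopy(self.gene_index)
        return m

    # -- views ---------------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return list(self.compounds)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S with one row per compound, one column per reaction."""
        cids = self.compound_ids
        rids = self.reaction_ids
        row = {cid: i for i, cid in enumerate(cids)}
        S = np.zeros((len(cids), len(rids)))
        for j, rid in enumerate(rids):
            for cid, coef in self.reactions[rid].stoichiometry.items():
                S[row[cid], j] = coef
        return S, cids, rids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions.values()])
        ub = np.array([r.ub for r in self.reactions.values()])
        return lb, ub

    def __repr__(self) -> str:
        return (f"<Model {self.id}: {len(self.compounds)} compounds, "
                f"{len(self.reactions)} reactions, "
                f"{len(genes_of(self))} genes>")


def genes_of(model: Model) -> set[str]:
    """Union of GPR leaves over all reactions."""
    out: set[str] = set()
    for r in model.reactions.values():
        out.update(r.gpr.leaves())
    return out


def reactions_for_genes(model: Model, genes: Iterable[str]) -> set[str]:
    """Reactions whose GPR mentions at least one of ``genes``.

    Membership is by association, not rule satisfaction: a reaction is
    included as soon as any queried gene appears among its GPR leaves.
    """
    gene_set = set(genes)
    return {rid for rid, r in model.reactions.items()
            if gene_set & r.gpr.genes()}


def validate_model(model: Model) -> list[str]:
    """Check model invariants; returns a list of violation messages.

    An empty report means the model is well-formed.  GPR leaves missing
    from the gene index are flagged but not fatal (the index may lag the
    rules during curation).
    """
    report: list[str] = []
    for rid, r in model.reactions.items():
        if not r.stoichiometry:
            report.append(f"reaction {rid}: empty stoichiometry")
        if r.lb > r.ub:
            report.append(f"reaction {rid}: lb {r.lb} > ub {r.ub}")
        for cid in r.stoichiometry:
            if cid not in model.compounds:
                report.append(f"reaction {rid}: unknown compound {cid!r}")
        if any(coef == 0 for coef in r.stoichiometry.values()):
            report.append(f"reaction {rid}: zero stoichiometric coefficient")
        if r.is_boundary and len(r.stoichiometry) != 1:
            report.append(
                f"reaction {rid}: {r.rclass} reaction must touch exactly one compound")
        for gene in r.gpr.genes():
            if model.gene_index and gene not in model.gene_index:
                report.append(f"reaction {rid}: gene {gene!r} not in gene index")
    for cid, c in model.compounds.items():
        suffix = compartment_of(cid)
        if suffix is not None and suffix != c.compartment:
            report.append(
                f"compound {cid}: id suffix [{suffix}] != compartment {c.compartment!r}")
    return report
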