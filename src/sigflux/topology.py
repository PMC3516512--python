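"""Structural network analyses.

Dead-end detection is purely structural (can a compound, given reaction
directionalities, be both produced and consumed at all?) while blocked
detection is flux-based (FVA range identically zero).  The two are
reported separately because they answer different questions: a dead-end
names the offending compound, a blocked reaction the functional loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx

from .core import Model, Reaction, UNBOUNDED, reactions_for_genes
from .lp import FEASIBILITY_TOL, fva

__all__ = [
    "SubNetwork", "find_dead_ends", "find_blocked_reactions",
    "add_exchanges_for_dead_ends", "connectivity", "extract_subnetwork",
    "export_graph", "to_bipartite_graph",
]


@dataclass
class SubNetwork:
    """A gene-set-induced sub-network of a parent model."""

    parent_model_id: str
    reaction_ids: set[str]
    compound_ids: set[str]
    inducing_genes: set[str]
    includes_outputs: set[str] = field(default_factory=set)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)


def find_dead_ends(model: Model, tol: float = FEASIBILITY_TOL) -> set[str]:
    """Compounds that cannot be both produced and consumed.

    A reversible reaction can serve either role for every compound it
    touches; an irreversible reaction produces its products and consumes
    its reactants.  Reactions pinned to zero (lb = ub = 0) count for
    neither role.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for r in model.reactions.values():
        fwd = r.ub > tol
        rev = r.lb < -tol
        for cid, coef in r.stoichiometry.items():
            if coef > 0:
                if fwd:
                    producible.add(cid)
                if rev:
                    consumable.add(cid)
            else:
                if fwd:
                    consumable.add(cid)
                if rev:
                    producible.add(cid)
    return {cid for cid in model.compounds
            if cid not in producible or cid not in consumable}


def find_blocked_reactions(model: Model, tol: float = FEASIBILITY_TOL) -> set[str]:
    """Reactions whose feasible flux range lies within +-tol of zero."""
    return fva(model).blocked(tol)


def add_exchanges_for_dead_ends(
    model: Model,
    selector: Callable[[str], bool] | None = None,
) -> tuple[Model, list[str]]:
    """Patch selected dead-end compounds with reversible exchanges.

    By default only extracellular dead-ends are patched (invading ligands
    and shed products legitimately cross the system boundary; a cytosolic
    dead-end usually signals a curation gap instead).  Returns the new
    model and the ids of the added exchange reactions.
    """
    if selector is None:
        selector = lambda cid: model.compounds[cid].compartment == "e"
    patched = model.copy()
    added: list[str] = []
    for cid in sorted(find_dead_ends(model)):
        if not selector(cid):
            continue
        base = "EX_" + cid
        rid = base
        k = 1
        while rid in patched.reactions:
            rid = f"{base}_{k}"
            k += 1
        patched.add_reaction(Reaction(rid, {cid: -1.0}, -UNBOUNDED, UNBOUNDED,
                                      rclass="exchange"))
        added.append(rid)
    return patched, added


def connectivity(model: Model, subnetwork: SubNetwork | None = None
                 ) -> dict[str, dict[str, float]]:
    """Compound degree and relative connectivity.

    Degree counts distinct reactions touching the compound; the ratio
    divides by the number of compounds in the entity itself (the whole
    model, or the sub-network when one is given), so parent and
    sub-network are compared on their own scales.
    """
    if subnetwork is None:
        cids: Iterable[str] = model.compounds
        rxns = model.reactions.values()
        denom = len(model.compounds)
    else:
        cids = subnetwork.compound_ids
        rxns = [model.reactions[rid] for rid in subnetwork.reaction_ids]
        denom = len(subnetwork.compound_ids)
    degree = {cid: 0 for cid in cids}
    for r in rxns:
        for cid in r.stoichiometry:
            if cid in degree:
                degree[cid] += 1
    return {cid: {"degree": d, "ratio": (d / denom if denom else 0.0)}
            for cid, d in degree.items()}


def extract_subnetwork(model: Model, genes: Iterable[str],
                       outputs: Iterable[str] = ()) -> SubNetwork:
    """Sub-network induced by a gene set.

    A reaction is included when at least one inducing gene appears in its
    GPR (association, not rule satisfaction); compounds are all
    participants of the included reactions.
    """
    gene_set = set(genes)
    rids = reactions_for_genes(model, gene_set)
    cids: set[str] = set()
    for rid in rids:
        cids.update(model.reactions[rid].stoichiometry)
    return SubNetwork(parent_model_id=model.id, reaction_ids=rids,
                      compound_ids=cids, inducing_genes=gene_set,
                      includes_outputs=set(outputs) & rids)


def to_bipartite_graph(model: Model, subnetwork: SubNetwork | None = None
                       ) -> nx.DiGraph:
    """Bipartite compound-reaction digraph (consumed -> reaction -> produced)."""
    if subnetwork is None:
        rids = model.reaction_ids
    else:
        rids = sorted(subnetwork.reaction_ids)
    g = nx.DiGraph()
    cids = sorted({cid for rid in rids
                   for cid in model.reactions[rid].stoichiometry})
    for cid in cids:
        g.add_node(cid, kind="compound")
    for rid in rids:
        g.add_node(rid, kind="reaction")
        for cid, coef in sorted(model.reactions[rid].stoichiometry.items()):
            if coef < 0:
                g.add_edge(cid, rid, coefficient=abs(coef))
            else:
                g.add_edge(rid, cid, coefficient=coef)
    return g


def export_graph(model: Model, path, subnetwork: SubNetwork | None = None) -> nx.DiGraph:
    """Write the bipartite graph as GraphML (``.graphml``) or an edge list."""
    g = to_bipartite_graph(model, subnetwork)
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tcoefficient\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{data.get('coefficient', 1)}\n")
    return g
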