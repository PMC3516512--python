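"""Readers and writers: tabular model dialect, SBML (L3 + FBC), data tables.

The canonical on-disk form of a model is a triple of UTF-8 TSV files
(reactions, compounds, genes) in the style of rBioNet flat files; lines
starting with ``#`` are comments.  SBML Level 3 with the FBC v2 package
is supported for interoperability (export plus basic import); the TSV
dialect remains authoritative.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import pandas as pd

from .core import Compound, Model, Reaction, UNBOUNDED, validate_model
from .gpr import parse_gpr, render_gpr

__all__ = [
    "read_model", "write_model", "export_sbml", "import_sbml",
    "read_expression", "read_diffexpr", "parse_formula", "format_formula",
]

_REACTION_COLS = ["id", "formula", "lb", "ub", "gpr", "rclass"]
_COMPOUND_COLS = ["id", "name", "compartment", "role"]
_GENE_COLS = ["gene_id", "symbol", "description"]

EXPRESSION_COLS = ["probe_id", "gene_id", "sample_id", "group", "detection_p", "intensity"]
DIFFEXPR_COLS = ["gene_id", "probe_id", "log2_fc", "fdr_p"]


class ModelFormatError(ValueError):
    pass


def _read_tsv(path, required: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelFormatError(f"{label} file {path}: missing column(s) {missing}")
    return df


def parse_formula(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``A[c] + 2 B[c] -> C[c]`` into (stoichiometry, reversible).

    ``->`` marks an irreversible, ``<=>`` a reversible reaction.  Either
    side may be empty (boundary reactions).  Coefficients default to 1.
    """
    if "<=>" in text:
        left, right = text.split("<=>", 1)
        reversible = True
    elif "->" in text:
        left, right = text.split("->", 1)
        reversible = False
    else:
        raise ModelFormatError(f"formula {text!r}: no '->' or '<=>' arrow")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                raise ModelFormatError(f"formula {text!r}: empty term")
            parts = term.split()
            if len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelFormatError(
                        f"formula {text!r}: bad coefficient {parts[0]!r}") from exc
                cid = parts[1]
            elif len(parts) == 1:
                coef, cid = 1.0, parts[0]
            else:
                raise ModelFormatError(f"formula {text!r}: malformed term {term!r}")
            stoich[cid] = stoich.get(cid, 0.0) + sign * coef
    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {cid: c for cid, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelFormatError(f"formula {text!r}: empty stoichiometry")
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(c)


def format_formula(stoichiometry: dict[str, float], reversible: bool) -> str:
    left, right = [], []
    for cid, coef in stoichiometry.items():
        target = left if coef < 0 else right
        mag = abs(coef)
        target.append(cid if mag == 1 else f"{_fmt_coef(mag)} {cid}")
    arrow = "<=>" if reversible else "->"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


def read_model(reactions_path, compounds_path, genes_path=None,
               model_id: str | None = None) -> Model:
    """Load a model from the TSV triple; validates before returning."""
    model = Model(model_id or Path(reactions_path).stem)
    cdf = _read_tsv(compounds_path, _COMPOUND_COLS, "compounds")
    for _, row in cdf.iterrows():
        model.add_compound(Compound(row["id"], row["name"],
                                    row["compartment"], row["role"]))
    if genes_path is not None:
        gdf = _read_tsv(genes_path, _GENE_COLS, "genes")
        for _, row in gdf.iterrows():
            model.gene_index[row["gene_id"]] = {
                "symbol": row["symbol"], "description": row["description"]}
    rdf = _read_tsv(reactions_path, _REACTION_COLS, "reactions")
    for _, row in rdf.iterrows():
        stoich, reversible = parse_formula(row["formula"])
        lb = float(row["lb"]) if row["lb"] != "" else (-UNBOUNDED if reversible else 0.0)
        ub = float(row["ub"]) if row["ub"] != "" else UNBOUNDED
        rxn = Reaction(row["id"], stoich, lb, ub, parse_gpr(row["gpr"]),
                       row["rclass"] or "core")
        model.add_reaction(rxn)
    problems = [p for p in validate_model(model) if "not in gene index" not in p]
    if problems:
        raise ModelFormatError("model failed validation:\n  " + "\n  ".join(problems))
    return model


def write_model(model: Model, reactions_path, compounds_path, genes_path=None) -> None:
    """Write the TSV triple; ``read_model`` round-trips it exactly."""
    rows = []
    for r in model.reactions.values():
        rows.append({"id": r.id,
                     "formula": format_formula(r.stoichiometry, r.reversible),
                     "lb": _fmt_coef(r.lb), "ub": _fmt_coef(r.ub),
                     "gpr": render_gpr(r.gpr), "rclass": r.rclass})
    pd.DataFrame(rows, columns=_REACTION_COLS).to_csv(reactions_path, sep="\t", index=False)
    crows = [{"id": c.id, "name": c.name, "compartment": c.compartment, "role": c.role}
             for c in model.compounds.values()]
    pd.DataFrame(crows, columns=_COMPOUND_COLS).to_csv(compounds_path, sep="\t", index=False)
    if genes_path is not None:
        grows = [{"gene_id": g, "symbol": info.get("symbol", ""),
                  "description": info.get("description", "")}
                 for g, info in model.gene_index.items()]
        pd.DataFrame(grows, columns=_GENE_COLS).to_csv(genes_path, sep="\t", index=False)


# ---------------------------------------------------------------- SBML

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str, mapping: dict[str, str]) -> str:
    safe = _SID_RE.sub("_", raw)
    if not safe or not (safe[0].isalpha() or safe[0] == "_"):
        safe = "_" + safe
    sid = prefix + safe
    mapping[sid] = raw
    return sid


def export_sbml(model: Model, path) -> dict[str, str]:
    """Write SBML Level 3 + FBC v2; returns the SId -> original-id map."""
    import libsbml

    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId(_SID_RE.sub("_", model.id) or "model")
    mplug = sbml.getPlugin("fbc")
    mplug.setStrict(False)
    mapping: dict[str, str] = {}

    compartments = sorted({c.compartment for c in model.compounds.values()} or {"c"})
    for comp in compartments:
        cc = sbml.createCompartment()
        cc.setId(comp)
        cc.setConstant(True)
    species_sid: dict[str, str] = {}
    for c in model.compounds.values():
        sp = sbml.createSpecies()
        sid = _sid("M_", c.id, mapping)
        species_sid[c.id] = sid
        sp.setId(sid)
        sp.setName(c.name or c.id)
        sp.setCompartment(c.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for g in sorted(set().union(*[r.gpr.genes() for r in model.reactions.values()])
                    if model.reactions else set()):
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", g, mapping))
        gp.setLabel(g)
        info = model.gene_index.get(g, {})
        if info.get("symbol"):
            gp.setName(info["symbol"])

    def bound_param(value: float) -> str:
        pid = "fb_" + _SID_RE.sub("_", repr(float(value))).replace("-", "m").replace(".", "p")
        if sbml.getParameter(pid) is None:
            p = sbml.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
        return pid

    for r in model.reactions.values():
        rx = sbml.createReaction()
        rx.setId(_sid("R_", r.id, mapping))
        rx.setFast(False)
        rx.setReversible(r.reversible)
        for cid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(species_sid[cid])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lb))
        rplug.setUpperFluxBound(bound_param(r.ub))
        if not r.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            rule = render_gpr(r.gpr)
            for g in r.gpr.genes():
                rule = re.sub(rf"(?<![\w]){re.escape(g)}(?![\w])",
                              _sid("G_", g, {}), rule)
            assoc.setAssociation(rule)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
    return mapping


def import_sbml(path) -> Model:
    """Basic SBML+FBC import (species, reactions, bounds, GPRs)."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelFormatError(f"SBML read error in {path}")
    sbml = doc.getModel()
    model = Model(sbml.getId() or Path(str(path)).stem)
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        model.add_compound(Compound(sp.getId(), sp.getName() or sp.getId(),
                                    sp.getCompartment() or "c"))
    mplug = sbml.getPlugin("fbc")
    label_of = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label_of[gp.getId()] = gp.getLabel() or gp.getId()
            model.gene_index[label_of[gp.getId()]] = {"symbol": gp.getName() or "",
                                                      "description": ""}
    for i in range(sbml.getNumReactions()):
        rx = sbml.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb = -UNBOUNDED if rx.getReversible() else 0.0
        ub = UNBOUNDED
        gpr = ""
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            for attr, into in ((rplug.getLowerFluxBound(), "lb"),
                               (rplug.getUpperFluxBound(), "ub")):
                if attr:
                    param = sbml.getParameter(attr)
                    if param is not None:
                        if into == "lb":
                            lb = param.getValue()
                        else:
                            ub = param.getValue()
            assoc = rplug.getGeneProductAssociation()
            if assoc is not None and assoc.getAssociation() is not None:
                gpr = assoc.getAssociation().toInfix()
                for sid, label in label_of.items():
                    gpr = re.sub(rf"(?<![\w]){re.escape(sid)}(?![\w])", label, gpr)
        model.add_reaction(Reaction(rx.getId(), stoich, lb, ub, parse_gpr(gpr)))
    return model


# ------------------------------------------------------------- data tables

def read_expression(path) -> pd.DataFrame:
    """Probe-level expression table with per-sample detection p-values."""
    df = _read_tsv(path, EXPRESSION_COLS, "expression")
    df = df.astype({"detection_p": float, "intensity": float})
    dup = df.duplicated(subset=["probe_id", "sample_id"])
    if dup.any():
        pairs = df.loc[dup, ["probe_id", "sample_id"]].values.tolist()
        raise ModelFormatError(f"duplicate (probe_id, sample_id) rows: {pairs}")
    bad_p = ~df["detection_p"].between(0.0, 1.0)
    if bad_p.any():
        raise ModelFormatError(
            f"detection_p outside [0,1] for probes {df.loc[bad_p, 'probe_id'].tolist()}")
    if (df["intensity"] < 0).any():
        raise ModelFormatError("negative intensity values")
    bad_group = ~df["group"].isin(["control", "treated"])
    if bad_group.any():
        raise ModelFormatError(
            f"unknown group labels {sorted(df.loc[bad_group, 'group'].unique())}")
    return df


def read_diffexpr(path) -> pd.DataFrame:
    """Differential-expression table: per-probe log2 FC and FDR-adjusted p."""
    df = _read_tsv(path, DIFFEXPR_COLS, "differential expression")
    df = df.astype({"log2_fc": float, "fdr_p": float})
    dup = df.duplicated(subset=["gene_id", "probe_id"])
    if dup.any():
        raise ModelFormatError("duplicate (gene_id, probe_id) rows")
    if (~df["fdr_p"].between(0.0, 1.0)).any():
        raise ModelFormatError("fdr_p outside [0,1]")
    return df
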