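#!/usr/bin/env python
"""Regenerate the miniTLR expectations file with an independent solver.

Reads the fixture's TSV tables, rebuilds the network inside cobrapy
(GLPK via optlang) and recomputes every committed expectation — FVA
ranges, blocked sets, dead-ends, sensitivity-curve points, co-stimulation
behavior, sub-network counts — without touching sigflux's own LP engine,
FVA, robustness or topology code.  Output is written to

    src/sigflux/data/minitlr/expectations.yaml

Run from the repository root:  python scripts/minitlr_oracle.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cobra
from cobra.flux_analysis import flux_variability_analysis

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "src" / "sigflux" / "data" / "minitlr"

SENSITIVITY_ENERGY = {"EX_atp[c]": (-25.0, 0.0), "EX_gtp[c]": (-25.0, 0.0)}
OUTPUTS = ["DM_NFKB[n]", "DM_AP1[n]", "DM_CREB[n]", "DM_IRF[n]", "DM_ROS[v]"]
IO_PAIRS = {
    "RECA": {"EX_ligA[e]": -1.0, "RECA_BIND": 1.0},
    "RECB": {"EX_ligB[e]": -1.0, "RECB_BIND": 1.0},
    "RECC": {"EX_ligC[e]": -1.0, "RECC_BIND": 1.0},
    "RECA+RECC": {"EX_ligA[e]": -1.0, "RECA_BIND": 1.0,
                  "EX_ligC[e]": -1.0, "RECC_BIND": 1.0},
}


def load_tables():
    rxns = pd.read_csv(DATA / "reactions.tsv", sep="\t", keep_default_na=False)
    comps = pd.read_csv(DATA / "compounds.tsv", sep="\t", keep_default_na=False)
    return rxns, comps


def parse_formula(text):
    arrow = "<=>" if "<=>" in text else "->"
    left, right = text.split(arrow)
    stoich = {}
    for side, sign in ((left, -1.0), (right, 1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split(" + "):
            parts = term.strip().split()
            coef, cid = (float(parts[0]), parts[1]) if len(parts) == 2 else (1.0, parts[0])
            stoich[cid] = stoich.get(cid, 0.0) + sign * coef
    return stoich


def build_cobra_model():
    rxns, comps = load_tables()
    model = cobra.Model("miniTLR_oracle")
    mets = {row["id"]: cobra.Metabolite(row["id"], compartment=row["compartment"])
            for _, row in comps.iterrows()}
    objects = []
    for _, row in rxns.iterrows():
        r = cobra.Reaction(row["id"])
        r.lower_bound, r.upper_bound = float(row["lb"]), float(row["ub"])
        objects.append(r)
    model.add_reactions(objects)
    for (_, row), r in zip(rxns.iterrows(), objects):
        r.add_metabolites({mets[cid]: coef
                           for cid, coef in parse_formula(row["formula"]).items()})
    return model, rxns, comps


def structural_dead_ends(rxns, comps):
    producible, consumable = set(), set()
    for _, row in rxns.iterrows():
        lb, ub = float(row["lb"]), float(row["ub"])
        for cid, coef in parse_formula(row["formula"]).items():
            if coef > 0:
                if ub > 0:
                    producible.add(cid)
                if lb < 0:
                    consumable.add(cid)
            else:
                if ub > 0:
                    consumable.add(cid)
                if lb < 0:
                    producible.add(cid)
    return sorted(set(comps["id"]) - (producible & consumable))


def configure(model, pair_name):
    """Close all ligand exchanges + bindings; apply one stimulation."""
    _, comps = load_tables()
    ligands = set(comps.loc[comps["role"] == "ligand", "id"])
    rxns, _ = load_tables()
    for _, row in rxns.iterrows():
        r = model.reactions.get_by_id(row["id"])
        if row["rclass"] == "binding":
            r.bounds = (0.0, 0.0)
        elif row["rclass"] == "exchange":
            met = next(iter(parse_formula(row["formula"])))
            if met in ligands:
                r.bounds = (0.0, 0.0)
    for rid, (lb, ub) in SENSITIVITY_ENERGY.items():
        model.reactions.get_by_id(rid).bounds = (lb, ub)
    if pair_name is not None:
        for rid, value in IO_PAIRS[pair_name].items():
            model.reactions.get_by_id(rid).bounds = (value, value)
    return model


def fva_dict(model, reactions=None):
    frame = flux_variability_analysis(
        model, reaction_list=reactions, fraction_of_optimum=0.0)
    return {rid: [round(float(row["minimum"]), 6) + 0.0,
                  round(float(row["maximum"]), 6) + 0.0]
            for rid, row in frame.iterrows()}


def robustness(model, control, objective, n_points, lb_lo, lb_hi):
    grid = np.linspace(lb_lo, lb_hi, n_points)
    out = []
    ctrl = model.reactions.get_by_id(control)
    model.objective = objective
    for g in grid:
        ctrl.bounds = (float(g), 0.0)
        val = model.slim_optimize(error_value=float("nan"))
        out.append(round(float(val), 6) + 0.0 if np.isfinite(val) else None)
    return [round(float(g), 6) for g in grid], out


def subnetwork_counts(rxns, genes):
    import re
    rids, cids = set(), set()
    for _, row in rxns.iterrows():
        leaves = set(re.findall(r"[\w\[\]]+", row["gpr"])) - {"and", "or"}
        if leaves & set(genes):
            rids.add(row["id"])
            cids.update(parse_formula(row["formula"]))
    return {"genes": sorted(genes), "n_reactions": len(rids),
            "n_compounds": len(cids), "reaction_ids": sorted(rids)}


def main():
    model, rxns, comps = build_cobra_model()
    exp = {}
    exp["dead_ends"] = structural_dead_ends(rxns, comps)
    raw_fva = fva_dict(model.copy())
    exp["blocked_raw"] = sorted(rid for rid, (lo, hi) in raw_fva.items()
                                if abs(lo) <= 1e-6 and abs(hi) <= 1e-6)
    exp["loop_fva_raw"] = {rid: raw_fva[rid] for rid in ("LOOP_F", "LOOP_R")}

    exp["output_fva"] = {}
    for pair in [None, "RECA", "RECB", "RECC", "RECA+RECC"]:
        key = pair or "baseline"
        exp["output_fva"][key] = fva_dict(configure(model.copy(), pair), OUTPUTS)

    exp["sensitivity_curves"] = []
    for pair, output, species, n_points, rng in [
        ("RECA", "DM_NFKB[n]", "EX_atp[c]", 6, (-25.0, 0.0)),
        ("RECA", "DM_NFKB[n]", "EX_gtp[c]", 6, (-25.0, 0.0)),
        ("RECA", "DM_NFKB[n]", "EX_atp[c]", 7, (-3.0, 0.0)),
        ("RECB", "DM_ROS[v]", "EX_gtp[c]", 6, (-25.0, 0.0)),
        ("RECB", "DM_ROS[v]", "EX_atp[c]", 7, (-2.0, 0.0)),
        ("RECA+RECC", "DM_IRF[n]", "EX_atp[c]", 7, (-6.0, 0.0)),
    ]:
        grid, resp = robustness(configure(model.copy(), pair), species,
                                output, n_points, *rng)
        exp["sensitivity_curves"].append({
            "pair": pair, "output": output, "control": species,
            "n_points": n_points, "lb_range": list(rng),
            "grid": grid, "responses": resp})

    exp["subnetworks"] = {
        "adaptor_isozymes": subnetwork_counts(rxns, ["201", "202"]),
        "cascade_isozymes": subnetwork_counts(rxns, ["401", "402", "403"]),
        "receptor_A": subnetwork_counts(rxns, ["101"]),
    }

    costim = fva_dict(configure(model.copy(), "RECA+RECC"), ["DM_IRF[n]"])
    single = fva_dict(configure(model.copy(), "RECA"), ["DM_IRF[n]"])
    exp["costimulation"] = {"irf_max_single": single["DM_IRF[n]"][1],
                            "irf_max_costim": costim["DM_IRF[n]"][1]}

    target = DATA / "expectations.yaml"
    header = ("# Brute-force expectations for the miniTLR fixture.\n"
              "# Generated by scripts/minitlr_oracle.py (cobrapy/GLPK);\n"
              "# do not edit by hand — rerun the script instead.\n")
    target.write_text(header + yaml.safe_dump(exp, sort_keys=True))
    print(f"wrote {target}")


if __name__ == "__main__":
    sys.exit(main())
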