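"""Generators for TLR-like benchmark networks and expression data.

The toy networks mirror the architecture of stoichiometric TLR signaling
reconstructions: ligand exchange -> receptor binding -> ATP-coupled
kinase cascade (OR across isozymes, AND for complexes) -> transcription
factor output demands, with optional planted dead-ends and internal
loops.  Every generator records its ground truth at construction time so
recovery can be tested exactly.

``mini_tlr`` loads the packaged static fixture: a hand-written ~35
reaction network with three receptors (one output requiring two-receptor
co-stimulation), a two-isozyme adaptor, an AND-complex kinase, a
GTP-coupled ROS branch, one internal loop and two extracellular
dead-ends.  Its expectations file is produced by an independent
brute-force script (``scripts/minitlr_oracle.py``) and shipped next to
the model tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .core import Compound, Model, Reaction, UNBOUNDED, genes_of
from .gpr import GPR_EMPTY, GprLeaf, GprNode, parse_gpr
from .iosim import IOPair

__all__ = [
    "ToyNetworkConfig", "GroundTruth", "generate_toy_network",
    "generate_expression_data", "generate_regulation",
    "generate_random_network", "generate_random_gpr", "mini_tlr", "mini_tlr_io",
    "mini_tlr_expectations",
]


@dataclass
class ToyNetworkConfig:
    n_receptors: int = 3
    cascade_depth: int = 3
    isozyme_multiplicity: int = 2
    n_outputs: int = 3
    energy_coupling: float = 1.0   # fraction of cascade steps consuming atp
    gtp_coupling: float = 0.0      # fraction of cascade steps also consuming gtp
    dead_end_fraction: float = 0.0
    loop_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_receptors, self.cascade_depth,
               self.isozyme_multiplicity, self.n_outputs) < 1:
            raise ValueError("counts must be >= 1")
        for frac in (self.energy_coupling, self.gtp_coupling, self.dead_end_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows about its own network."""

    reachability: dict[tuple[str, str], bool] = field(default_factory=dict)
    expected_yields: dict[tuple[str, str], float] = field(default_factory=dict)
    essential_genes_per_output: dict[str, set[str]] = field(default_factory=dict)
    absent_genes: set[str] = field(default_factory=set)
    io_pairs: list[IOPair] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    planted_dead_ends: set[str] = field(default_factory=set)
    loop_reactions: set[str] = field(default_factory=set)


def generate_toy_network(config: ToyNetworkConfig) -> tuple[Model, GroundTruth]:
    """Deterministically build a receptor->cascade->output toy network."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = Model(f"toy_seed{config.seed}")
    truth = GroundTruth()

    def add_compound(cid, name, comp, role):
        if cid not in model.compounds:
            model.add_compound(Compound(cid, name, comp, role))

    needs_atp = config.energy_coupling > 0
    needs_gtp = config.gtp_coupling > 0
    if needs_atp:
        add_compound("atp[c]", "ATP", "c", "metabolite")
        add_compound("adp[c]", "ADP", "c", "metabolite")
        model.add_reaction(Reaction("EX_atp[c]", {"atp[c]": -1.0},
                                    -UNBOUNDED, UNBOUNDED, rclass="exchange"))
        model.add_reaction(Reaction("SK_adp[c]", {"adp[c]": -1.0},
                                    0.0, UNBOUNDED, rclass="sink"))
    if needs_gtp:
        add_compound("gtp[c]", "GTP", "c", "metabolite")
        add_compound("gdp[c]", "GDP", "c", "metabolite")
        model.add_reaction(Reaction("EX_gtp[c]", {"gtp[c]": -1.0},
                                    -UNBOUNDED, UNBOUNDED, rclass="exchange"))
        model.add_reaction(Reaction("SK_gdp[c]", {"gdp[c]": -1.0},
                                    0.0, UNBOUNDED, rclass="sink"))

    terminal: list[str] = []
    chain_genes: list[set[str]] = []   # essential (single-copy) genes per chain
    gene_counter = [1000]

    def fresh_genes(k: int) -> list[str]:
        ids = [str(gene_counter[0] + i) for i in range(k)]
        gene_counter[0] += k
        for g in ids:
            model.gene_index[g] = {"symbol": f"G{g}", "description": "synthetic gene"}
        return ids

    for i in range(config.n_receptors):
        lig = f"lig{i}[e]"
        add_compound(lig, f"ligand {i}", "e", "ligand")
        model.add_reaction(Reaction(f"EX_lig{i}[e]", {lig: -1.0},
                                    -UNBOUNDED, UNBOUNDED, rclass="exchange"))
        (rec_gene,) = fresh_genes(1)
        s0 = f"s{i}_0[c]"
        add_compound(s0, f"receptor {i} signal", "c", "complex")
        model.add_reaction(Reaction(f"BIND_R{i}", {lig: -1.0, s0: 1.0},
                                    0.0, UNBOUNDED, GprLeaf(rec_gene), "binding"))
        model.add_reaction(Reaction(f"DEG_S{i}", {s0: -1.0},
                                    0.0, UNBOUNDED, rclass="sink"))
        essential = {rec_gene}
        prev = s0
        for j in range(1, config.cascade_depth + 1):
            cur = f"s{i}_{j}[c]"
            add_compound(cur, f"cascade {i} level {j}", "c", "kinase")
            stoich = {prev: -1.0, cur: 1.0}
            if needs_atp and rng.random() < config.energy_coupling:
                stoich.update({"atp[c]": -1.0, "adp[c]": 1.0})
            if needs_gtp and rng.random() < config.gtp_coupling:
                stoich.update({"gtp[c]": -1.0, "gdp[c]": 1.0})
            if j % 3 == 2:  # complex step: every subunit required
                genes = fresh_genes(2)
                gpr = GprNode("and", tuple(GprLeaf(g) for g in genes))
                essential.update(genes)
            else:           # isozyme step: any one gene suffices
                genes = fresh_genes(config.isozyme_multiplicity)
                if len(genes) == 1:
                    gpr = GprLeaf(genes[0])
                    essential.update(genes)
                else:
                    gpr = GprNode("or", tuple(GprLeaf(g) for g in genes))
            model.add_reaction(Reaction(f"STEP_{i}_{j}", stoich, 0.0, UNBOUNDED, gpr))
            prev = cur
        terminal.append(prev)
        chain_genes.append(essential)
        truth.io_pairs.append(IOPair(f"R{i}", (f"EX_lig{i}[e]",), (f"BIND_R{i}",)))

    for k in range(config.n_outputs):
        i = k % config.n_receptors
        out_c = f"o{k}[n]"
        add_compound(out_c, f"active TF {k}", "n", "protein")
        (tf_gene,) = fresh_genes(1)
        model.add_reaction(Reaction(f"ACT_{k}", {terminal[i]: -1.0, out_c: 1.0},
                                    0.0, UNBOUNDED, GprLeaf(tf_gene)))
        dm = f"DM_OUT{k}[n]"
        model.add_reaction(Reaction(dm, {out_c: -1.0}, 0.0, UNBOUNDED,
                                    rclass="demand"))
        truth.outputs.append(dm)
        truth.essential_genes_per_output[dm] = chain_genes[i] | {tf_gene}
        for r in range(config.n_receptors):
            reachable = (r == i)
            truth.reachability[(f"R{r}", dm)] = reachable
            truth.expected_yields[(f"R{r}", dm)] = 1.0 if reachable else 0.0

    n_dead = int(round(config.dead_end_fraction * config.n_receptors))
    for d in range(n_dead):
        orph = f"orph{d}[e]"
        add_compound(orph, f"orphan ligand {d}", "e", "ligand")
        (g,) = fresh_genes(1)
        model.add_reaction(Reaction(f"ORPH_BIND{d}",
                                    {orph: -1.0, f"s{d % config.n_receptors}_0[c]": 1.0},
                                    0.0, UNBOUNDED, GprLeaf(g), "binding"))
        truth.planted_dead_ends.add(orph)

    for m in range(config.loop_count):
        x, y = f"lpx{m}[c]", f"lpy{m}[c]"
        add_compound(x, f"loop {m} X", "c", "protein")
        add_compound(y, f"loop {m} Y", "c", "protein")
        model.add_reaction(Reaction(f"LOOP_F{m}", {x: -1.0, y: 1.0}, 0.0, 10.0))
        model.add_reaction(Reaction(f"LOOP_R{m}", {y: -1.0, x: 1.0}, 0.0, 10.0))
        truth.loop_reactions.update({f"LOOP_F{m}", f"LOOP_R{m}"})
    return model, truth


def generate_expression_data(model: Model, absent_fraction: float = 0.2,
                             noise: float = 0.0, n_samples: int = 3,
                             seed: int = 0, multi_probe_fraction: float = 0.3
                             ) -> tuple[pd.DataFrame, set[str]]:
    """Probe-level detection data with a planted absent gene set.

    At zero noise present genes receive detection p = 0 and absent genes
    p = 1 on every sample, so any cutoff in (0, 1) recovers the planted
    truth exactly.  Noise adds Gaussian jitter (clipped to [0, 1]) so
    calls can flip near the cutoff.  Intensities correlate with
    presence; a fraction of genes gets a second, dimmer probe.
    """
    if not 0.0 <= absent_fraction <= 1.0:
        raise ValueError("absent_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(genes_of(model))
    n_absent = int(round(absent_fraction * len(genes)))
    absent = set(rng.choice(genes, size=n_absent, replace=False)) if n_absent else set()
    samples = [("control", f"c{k}") for k in range(n_samples)] + \
              [("treated", f"t{k}") for k in range(n_samples)]
    rows = []
    for gene in genes:
        is_absent = gene in absent
        n_probes = 2 if rng.random() < multi_probe_fraction else 1
        for p in range(n_probes):
            probe = f"{gene}_at{p}"
            base_int = (80.0 if is_absent else 5000.0) / (1.0 + p)
            for group, sample in samples:
                target = 1.0 if is_absent else 0.0
                detp = target if noise == 0.0 else float(
                    np.clip(target + rng.normal(0.0, noise) * (-1 if is_absent else 1),
                            0.0, 1.0))
                rows.append({"probe_id": probe, "gene_id": gene,
                             "sample_id": sample, "group": group,
                             "detection_p": detp,
                             "intensity": float(abs(rng.normal(base_int, base_int * 0.05)))})
    return pd.DataFrame(rows), absent


def generate_regulation(model: Model, n_up: int = 4, n_down: int = 2,
                        fc_range: tuple[float, float] = (2.0, 8.0),
                        seed: int = 0, probes_per_gene: int = 2
                        ) -> tuple[pd.DataFrame, "RegulationSet"]:
    """Differential-expression table with planted up/down regulation."""
    from .contextualize import RegulationSet

    rng = np.random.default_rng(seed)
    genes = sorted(genes_of(model))
    if n_up + n_down > len(genes):
        raise ValueError("n_up + n_down exceeds gene count")
    chosen = rng.choice(genes, size=n_up + n_down, replace=False)
    up_genes, down_genes = set(chosen[:n_up]), set(chosen[n_up:])
    lo, hi = np.log2(fc_range[0]), np.log2(fc_range[1])
    truth = RegulationSet()
    rows = []
    for gene in genes:
        fcs = []
        for p in range(probes_per_gene):
            if gene in up_genes:
                l2fc = float(rng.uniform(lo, hi))
                fdr = float(rng.uniform(1e-6, 1e-3))
            elif gene in down_genes:
                l2fc = -float(rng.uniform(lo, hi))
                fdr = float(rng.uniform(1e-6, 1e-3))
            else:
                l2fc = float(np.clip(rng.normal(0.0, 0.2), -0.9, 0.9))
                fdr = float(rng.uniform(0.1, 0.95))
            fcs.append(l2fc)
            rows.append({"gene_id": gene, "probe_id": f"{gene}_at{p}",
                         "log2_fc": l2fc, "fdr_p": fdr})
        if gene in up_genes:
            truth.up[gene] = float(np.mean(2.0 ** np.array(fcs)))
        elif gene in down_genes:
            truth.down[gene] = float(np.mean(2.0 ** (-np.array(fcs))))
    return pd.DataFrame(rows), truth


def generate_random_network(rng: np.random.Generator, max_reactions: int = 6,
                            max_compounds: int = 4) -> Model:
    """Small random stoichiometric network for solver cross-checks.

    Bounds always contain zero, so the zero flux vector is feasible and
    the network is never infeasible.  Sizes stay small enough for the
    brute-force vertex-enumeration reference.
    """
    n_r = int(rng.integers(2, max_reactions + 1))
    n_c = int(rng.integers(1, max_compounds + 1))
    model = Model(f"random_{rng.integers(1 << 30)}")
    for i in range(n_c):
        model.add_compound(Compound(f"x{i}[c]", f"x{i}", "c", "metabolite"))
    bound_menu = [(-10.0, 10.0), (0.0, 10.0), (-5.0, 5.0), (0.0, 5.0), (-5.0, 0.0)]
    for j in range(n_r):
        stoich = {}
        for i in range(n_c):
            if rng.random() < 0.5:
                coef = float(rng.choice([-2, -1, 1, 2]))
                stoich[f"x{i}[c]"] = coef
        if not stoich:
            stoich[f"x{int(rng.integers(n_c))}[c]"] = float(rng.choice([-1, 1]))
        lb, ub = bound_menu[int(rng.integers(len(bound_menu)))]
        model.add_reaction(Reaction(f"r{j}", stoich, lb, ub))
    return model


# ----------------------------------------------------------- fixtures

def _data_dir():
    return resources.files("sigflux") / "data" / "minitlr"


def mini_tlr() -> Model:
    """Load the packaged miniTLR fixture model."""
    from .io import read_model

    d = _data_dir()
    with resources.as_file(d / "reactions.tsv") as rp, \
            resources.as_file(d / "compounds.tsv") as cp, \
            resources.as_file(d / "genes.tsv") as gp:
        return read_model(rp, cp, gp, model_id="miniTLR")


def mini_tlr_io() -> tuple[list[IOPair], list[str]]:
    """The fixture's I/O configuration: four inputs, five outputs."""
    rec_a = IOPair("RECA", ("EX_ligA[e]",), ("RECA_BIND",))
    rec_b = IOPair("RECB", ("EX_ligB[e]",), ("RECB_BIND",))
    rec_c = IOPair("RECC", ("EX_ligC[e]",), ("RECC_BIND",))
    costim = IOPair("RECA+RECC", ("EX_ligA[e]",), ("RECA_BIND",),
                    co_stimulation=IOPair("RECC", ("EX_ligC[e]",), ("RECC_BIND",)))
    outputs = ["DM_NFKB[n]", "DM_AP1[n]", "DM_CREB[n]", "DM_IRF[n]", "DM_ROS[v]"]
    return [rec_a, rec_b, rec_c, costim], outputs


def mini_tlr_expectations() -> dict:
    """Committed brute-force expectations for the fixture."""
    with resources.as_file(_data_dir() / "expectations.yaml") as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def generate_random_gpr(rng: np.random.Generator, max_leaves: int = 10):
    """Random GPR tree over genes g0..g{k-1} for evaluator cross-checks."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    genes = [f"g{i}" for i in range(n_leaves)]
    pool = [GprLeaf(g) for g in genes]
    rng.shuffle(pool)
    while len(pool) > 1:
        k = int(rng.integers(2, min(4, len(pool)) + 1))
        children = [pool.pop() for _ in range(k)]
        op = "and" if rng.random() < 0.5 else "or"
        pool.append(GprNode(op, tuple(children)))
    return pool[0], genes
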