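"""Input/output-relationship harness.

An I/O relationship pairs a receptor stimulation configuration (a ligand
exchange fixed to uptake one unit plus the corresponding ligand-receptor
binding reaction fixed to carry one unit) with one signaling output
(demand) reaction.  Every other ligand exchange and binding reaction is
closed, so each relationship isolates a single receptor's contribution.
Energy availability is set per scenario: the sensitivity scans supply
ATP and GTP at up to 25 units each, the quantitative fold-change mapping
at 100 (ATP) and 50 (GTP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Model
from .lp import FEASIBILITY_TOL, SensitivityCurve, fva, robustness_scan

__all__ = [
    "IOPair", "IOMatrix", "ENERGY_SCENARIOS", "energy_exchanges",
    "configure_io", "enumerate_io_relationships", "output_capability_matrix",
    "sensitivity_analysis", "load_io_config", "tlr_reference_io",
]

#: Energy-exchange lower bounds (uptake) per named scenario; ub is 0.
ENERGY_SCENARIOS: dict[str, dict[str, float]] = {
    "sensitivity": {"atp": -25.0, "gtp": -25.0},
    "quantitative": {"atp": -100.0, "gtp": -50.0},
}


@dataclass
class IOPair:
    """One receptor stimulation configuration.

    ``exchange_rxns`` are fixed to lb = ub = -1 (one unit of ligand
    uptake), ``binding_rxns`` to lb = ub = 1.  ``co_stimulation`` nests a
    second configuration for outputs that need two receptors at once.
    """

    input_id: str
    exchange_rxns: tuple[str, ...]
    binding_rxns: tuple[str, ...]
    output_rxn: str = ""
    co_stimulation: "IOPair | None" = None

    def all_fixed_reactions(self) -> dict[str, float]:
        fixed = {rid: -1.0 for rid in self.exchange_rxns}
        fixed.update({rid: 1.0 for rid in self.binding_rxns})
        if self.co_stimulation is not None:
            fixed.update(self.co_stimulation.all_fixed_reactions())
        return fixed


@dataclass
class IOMatrix:
    """FVA output ranges per (input, output), with baseline subtraction."""

    fva_min: pd.DataFrame
    fva_max: pd.DataFrame
    baseline_max: pd.Series
    delta_over_baseline: pd.DataFrame


def _ligand_io_reactions(model: Model) -> list[str]:
    """All ligand exchange reactions and all binding reactions."""
    out = []
    for rid, r in model.reactions.items():
        if r.rclass == "binding":
            out.append(rid)
        elif r.rclass == "exchange":
            (cid,) = r.stoichiometry
            if model.compounds[cid].role == "ligand":
                out.append(rid)
    return out


def energy_exchanges(model: Model) -> dict[str, str]:
    """Map energy species (atp/gtp) to its exchange reaction id."""
    found: dict[str, str] = {}
    for rid, r in model.reactions.items():
        if r.rclass != "exchange":
            continue
        (cid,) = r.stoichiometry
        base = cid.split("[")[0].lower()
        if base in ("atp", "gtp"):
            found[base] = rid
    return found


def configure_io(model: Model, pair: IOPair | None,
                 energy: str | Mapping[str, float] = "sensitivity") -> Model:
    """Return a copy of the model configured for one I/O relationship.

    All ligand exchanges and binding reactions are closed; the pair's
    exchange reactions are fixed at -1 and binding reactions at 1
    (co-stimulation recursively).  ``pair=None`` yields the baseline
    state with every input closed.  ``energy`` names a scenario or maps
    energy species to uptake lower bounds.
    """
    cfg = model.copy()
    for rid in _ligand_io_reactions(cfg):
        cfg.reactions[rid].lb = 0.0
        cfg.reactions[rid].ub = 0.0
    if pair is not None:
        for rid, value in pair.all_fixed_reactions().items():
            if rid not in cfg.reactions:
                raise KeyError(f"I/O pair {pair.input_id}: unknown reaction {rid!r}")
            cfg.reactions[rid].lb = value
            cfg.reactions[rid].ub = value
    bounds = ENERGY_SCENARIOS[energy] if isinstance(energy, str) else dict(energy)
    ex = energy_exchanges(cfg)
    for species, lb in bounds.items():
        if species in ex:
            cfg.reactions[ex[species]].lb = lb
            cfg.reactions[ex[species]].ub = 0.0
    return cfg


def enumerate_io_relationships(inputs: Sequence[IOPair], outputs: Sequence[str]
                               ) -> list[tuple[IOPair, str]]:
    """Full Cartesian product of inputs and outputs, in given order."""
    return [(pair, out) for pair in inputs for out in outputs]


def output_capability_matrix(model: Model, pairs: Sequence[IOPair],
                             outputs: Sequence[str],
                             energy: str | Mapping[str, float] = "sensitivity"
                             ) -> IOMatrix:
    """FVA of every output under every stimulation, minus baseline.

    The baseline row is computed with all inputs closed; internal loops
    through an output show up there and are subtracted out, so the delta
    isolates the stimulation effect.  Per-cell infeasibility is recorded
    as NaN.
    """
    outputs = list(outputs)
    base = configure_io(model, None, energy)
    try:
        base_fva = fva(base, outputs)
        baseline = pd.Series({o: base_fva.maximum(o) for o in outputs})
    except RuntimeError:
        baseline = pd.Series({o: np.nan for o in outputs})
    rows_min, rows_max = [], []
    for pair in pairs:
        cfg = configure_io(model, pair, energy)
        try:
            result = fva(cfg, outputs)
            rows_min.append({o: result.minimum(o) for o in outputs})
            rows_max.append({o: result.maximum(o) for o in outputs})
        except RuntimeError:
            rows_min.append({o: np.nan for o in outputs})
            rows_max.append({o: np.nan for o in outputs})
    index = [p.input_id for p in pairs]
    fmin = pd.DataFrame(rows_min, index=index, columns=outputs)
    fmax = pd.DataFrame(rows_max, index=index, columns=outputs)
    return IOMatrix(fmin, fmax, baseline, fmax.sub(baseline, axis=1))


def sensitivity_analysis(model: Model, pair: IOPair, energy_species: str = "atp",
                         n_points: int = 50,
                         lb_range: Sequence[float] = (-25.0, 0.0),
                         output_rxn: str | None = None) -> SensitivityCurve:
    """Robustness scan of an output versus ATP or GTP availability.

    The model is configured for the given I/O relationship with both
    energy exchanges at the sensitivity-scenario bounds, then the chosen
    energy exchange's lower bound is swept over the grid while the
    output flux is maximized.
    """
    output = output_rxn or pair.output_rxn
    if not output:
        raise ValueError("no output reaction given (pair.output_rxn empty)")
    cfg = configure_io(model, pair, "sensitivity")
    ex = energy_exchanges(cfg)
    if energy_species not in ex:
        raise KeyError(f"no exchange reaction found for energy species {energy_species!r}")
    return robustness_scan(cfg, ex[energy_species], output, n_points, lb_range)


# ------------------------------------------------------------- configuration

def _pair_from_dict(entry: Mapping) -> IOPair:
    co = entry.get("co_stimulation")
    return IOPair(
        input_id=entry["input_id"],
        exchange_rxns=tuple(entry.get("exchange", ())),
        binding_rxns=tuple(entry.get("binding", ())),
        output_rxn=entry.get("output", ""),
        co_stimulation=_pair_from_dict(co) if co else None,
    )


def load_io_config(path) -> tuple[list[IOPair], list[str]]:
    """Read an I/O configuration file (YAML: ``inputs`` and ``outputs``)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    pairs = [_pair_from_dict(e) for e in cfg.get("inputs", [])]
    outputs = list(cfg.get("outputs", []))
    return pairs, outputs


def tlr_reference_io() -> tuple[list[IOPair], list[str]]:
    """The packaged human-TLR-network I/O configuration (13 inputs, 9 outputs)."""
    from importlib import resources

    ref = resources.files("sigflux") / "data" / "tlr_io_config.yaml"
    with resources.as_file(ref) as p:
        return load_io_config(p)
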