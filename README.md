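# sigflux

Constraint-based modeling (COBRA) of **stoichiometric signaling
networks**, with transcriptomics-driven contextualization. The package
targets networks like the Toll-like receptor (TLR) cascade, written as a
stoichiometric matrix **S** over chemical compounds (receptors, kinases,
phosphatases, ligands, complexes, metabolites) and reactions (binding,
phosphorylation, transport, exchange/demand/sink), each reaction carrying
flux bounds *lb ≤ v ≤ ub* and a Boolean gene–reaction association (GPR:
`AND` for complexes, `OR` for isoforms). It is intended for systems
biologists who want to ask what a signaling network can *do* in a given
cell type or stimulation condition without kinetic parameters.

## What it computes

All simulation rests on the steady-state flux polytope
{ v : S·v = 0, lb ≤ v ≤ ub }:

- **FBA** — maximize or minimize one reaction flux (scipy HiGHS);
  **parsimonious FBA** — re-minimize total flux Σ|vᵢ| (L1, split-variable
  LP) at the fixed optimum, suppressing arbitrary loop fluxes;
  **FVA** — per-reaction feasible flux ranges; **robustness scans** —
  max output flux while sweeping an energy-exchange lower bound.
- **Topology** — dead-end compounds (cannot be both produced and
  consumed), blocked reactions (FVA range ≡ 0), dead-end exchange
  patching, compound connectivity, gene-set-induced sub-networks with
  GraphML export.
- **Contextualization** — the pipeline from probe-level expression data
  to a condition-specific model:
  1. presence/absence calls per gene at a detection-p cutoff (one probe
     per gene, highest mean control intensity; majority rule across
     samples);
  2. tailoring: a reaction is disabled (lb = ub = 0) only when its whole
     GPR is unsatisfied — an isoform reaction survives while any one
     isoform is present;
  3. condition tailoring that never re-adds genes absent from the base;
  4. differential-expression calls (|FC| ≥ 2, FDR p < 0.05 for ≥ 50 % of
     a gene's probes), reaction fold changes FCrxn (mean over regulated
     genes), and bound mapping against a parsimonious reference flux
     v_ref: up-regulation raises lbᵢ to (FCrxn⁄FC-up)·v_ref,i, down-
     regulation scales ubᵢ by (1 − FCrxn⁄FC-down);
  5. I/O gap diagnosis and single-gene reintroduction scans.
- **I/O harness** — receptor stimulation protocol (ligand exchange fixed
  at −1, binding reaction at +1, all other inputs closed; co-stimulation
  supported), output-capability matrices with baseline subtraction, and
  ATP/GTP sensitivity classification.
- **Synthetic benchmarks** — seeded TLR-like toy network generators with
  recorded ground truth, plus the packaged `miniTLR` fixture whose
  expectations file is produced by an independent brute-force script.

## Worked example

```python
import sigflux as sf

model = sf.mini_tlr()
print(model)
# <Model miniTLR: 28 compounds, 36 reactions, 14 genes>

# tailor to a context where one kinase-complex subunit is missing
result = sf.tailor_model(model, {"302": False})
print(sorted(result.disabled_reactions))
# ['KIN_A', 'KIN_B', 'KIN_C']
print(result.stats)
# {'n_deleted_genes': 1, 'n_constrained_reactions': 3, 'n_dead_ends': 8, 'n_blocked': 25}

# which outputs can each receptor drive?
pairs, outputs = sf.mini_tlr_io()
mat = sf.output_capability_matrix(model, pairs, outputs)
print(mat.fva_max.round(2))
#            DM_NFKB[n]  DM_AP1[n]  DM_CREB[n]  DM_IRF[n]  DM_ROS[v]
# RECA              1.0        0.0         1.0        0.0        0.0
# RECB              0.0        1.0         0.0        0.0        1.0
# RECC              0.0        0.0         0.0        0.0        0.0
# RECA+RECC         1.0        0.0         1.0        1.0        0.0

curve = sf.sensitivity_analysis(model, pairs[1], "gtp",
                                n_points=6, output_rxn="DM_ROS[v]")
print(curve.responses.round(2), "->", curve.classify())
# [1. 1. 1. 1. 1. 0.] -> dependent
```

Losing one subunit of the AND-complex kinase kills all three branches
downstream (25 of 36 reactions end up blocked). Receptor A drives NF-κB
and CREB, receptor B drives AP-1 and ROS, and the IRF output appears only
under A+C co-stimulation. ROS production collapses as GTP uptake is
closed, so the output classifies as GTP-*dependent*; the same scan
against an output with no GTP in its path stays flat (*independent*).

A `sigflux` command-line tool mirrors the library (`validate`, `tailor`,
`iomatrix`, `sensitivity`, `subnet`, `simulate`); numeric reports are
written as TSV files together with a run manifest.

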