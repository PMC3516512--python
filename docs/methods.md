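# Methods

## Model and assumptions

A signaling network is treated the way constraint-based metabolic models
are: a stoichiometric matrix **S** (rows: chemical compounds; columns:
reactions), finite flux bounds per reaction, and the steady-state
assumption S·v = 0. "Flux" through a signaling reaction is an abstract
signal-propagation rate in arbitrary units; inputs supply one unit of
ligand (exchange fixed at −1 together with its receptor-binding reaction
at +1), and outputs are demand reactions draining activated
transcription factors (nuclear compartment) or effector species such as
ROS (vesicular compartment). No kinetics, concentrations, or time are
represented: every statement is about *capability* — which outputs a
given input can drive, and at what maximal rate, under the imposed
exchange bounds.

Compartments are encoded as bracket suffixes on compound ids
(`atp[c]`, `DM_IRF[n]`-style reaction names), with `e`/`c`/`n`/`v` for
extracellular, cytosol, nucleus, vesicle. The finite stand-in for an
unconstrained bound is ±1000: large against every meaningful supply
bound used here (1, 25, 50, 100) and conventional for LP-based COBRA
stacks.

Gene–reaction associations are Boolean trees: `AND` joins complex
subunits or jointly required proteins, `OR` joins functional isoforms.
The central tailoring rule follows from the OR semantics: a reaction is
disabled only when *no* satisfying assignment remains under the
present/absent calls, i.e. an isozyme reaction dies only when every
isoform is absent. Reactions with no association (boundary reactions,
generic transport, orphan compounds) are never disabled by data mapping.

## Linear programming

All solves use `scipy.optimize.linprog` (HiGHS). Choices that matter:

- **Parsimonious FBA as L1.** After fixing the objective flux at its
  optimum, total flux Σ|vᵢ| is minimized via an auxiliary LP
  (t ≥ v, t ≥ −v, minimize Σt). The classical `minNorm` option of the
  MATLAB COBRA toolbox minimizes the Euclidean norm, which needs a QP
  solver; the L1 form serves the same purpose here — choosing one
  representative flux vector and silencing futile loop flux — while
  keeping the stack purely linear. Flux values of the representative
  vector can differ from the L2 choice when alternative optima exist;
  only loop suppression and the objective value are relied upon.
- **FVA without objective fixation.** Output-capability questions are
  about the whole feasible set under the I/O constraints, so FVA here
  runs 2 LPs per reaction over the unrestricted polytope (a
  fraction-of-optimum variant is deliberately not the default).
- **Tolerances.** 1e−6 flux units for feasibility, blocked
  classification, and energy-dependence classification; solver defaults
  otherwise. FVA results are clipped to the reaction bounds to remove
  solver jitter, and negative zeros are normalized.
- **Loops are kept.** Internal cycles are structurally legitimate in
  signaling reconstructions (activation/deactivation cycles), so no
  loopless correction is applied anywhere. Consequences are handled
  downstream: baseline subtraction in the I/O matrix removes loop-borne
  output flux, and parsimonious FBA picks loop-free representatives.
- **Infeasibility is data, not an error,** in scans: a robustness grid
  point or I/O matrix cell that is infeasible is recorded as NaN and the
  scan continues. Whole-model infeasibility in FVA raises.

## Contextualization pipeline

**Presence/absence.** Detection p-values are consumed as provided (their
computation from raw arrays is upstream of this package). Per gene, the
probe with the highest mean intensity in the control group is selected;
the gene is present when that probe's detection p falls below the cutoff
in a majority of the group's samples (configurable to any/all; the
majority default is the middle ground between the two). Two cutoffs
(loose 0.02, stringent 0.01 by default — both exposed, since the
procedure rather than the constants is what matters) support the
two-model comparison report. Genes missing from a call map default to
*present*: probe coverage gaps must not silently delete reactions, and
the calling convention biases the same way.

**Tailoring.** Disabling means pinning lb = ub = 0 rather than deleting,
so tailoring is trivially idempotent, reversible, and preserves the
matrix shape. Tailoring statistics (absent genes, constrained reactions,
dead-ends, blocked reactions) are recomputed from the tailored model.
Condition tailoring merges the base model's absent set with the
condition's newly absent genes and ignores genes that reappear: a gene
dropped at the cell-type stage stays out, because in the cases that
motivate the rule an isoform partner already carries its reactions.

**Differential expression and bound mapping.** A probe is regulated at
|FC| ≥ 2 and FDR p < 0.05; a gene needs ≥ 50 % of its probes regulated
in one direction, otherwise it is *subthreshold* (genes with probes
regulated in both directions are subthreshold with a warning). Reaction
fold change FCrxn is the arithmetic mean over the reaction's regulated
genes; the data-set maxima FC-up / FC-down act as scaling references.
Bounds move relative to a parsimonious reference flux distribution
v_ref computed under the same I/O configuration:

- up-regulated, v_ref,i > 0: lbᵢ ← max(lbᵢ, (FCrxn⁄FC-up)·v_ref,i)
  (mirrored onto ubᵢ for negative reference flux; untouched at zero) —
  at FCrxn = FC-up the reference flux is fully enforced;
- down-regulated, v_ref,i ≥ 0: ubᵢ ← (1 − FCrxn⁄FC-down)·ubᵢ (mirrored
  lb for negative flux) — at FCrxn = FC-down the reaction closes.

The exact algebraic form of the published bound-update equations is not
recoverable from the source text available here; the implementation
realizes the verbal contract (enforce minimum flux / reduce maximum
flux, scaled by the reference fold change) and is isolated in a single
function so an alternative form can be swapped in. If an adjustment
would cross lb > ub it is clipped with a warning. Reactions carrying
both up- and down-regulated genes are excluded with a warning; the rule
never has to fire on data shaped like the motivating case (no
down-regulated isoforms).

**Gap repair.** The participating set of a model for an I/O pair is the
set of reactions able to carry flux while the output is forced to one
unit (FVA with output lb = 1) — a deterministic replacement for
interactive pathway inspection. Reactions participating in the reference
but disabled in a draft are the missing links; their absent GPR genes
are candidates, and a per-gene reintroduction scan reports each
candidate's single-handed effect on output capability.

## I/O harness

`configure_io` always works on a copy: all ligand exchanges (exchange
reactions whose single compound has the ligand role) and all binding
reactions are closed, the chosen pair is fixed (uptake negative by
convention), co-stimulation nests recursively, and energy exchanges are
set per scenario — sensitivity: ATP and GTP lb = −25, ub = 0;
quantitative mapping: ATP lb = −100, GTP lb = −50, ub = 0. Robustness
scans sweep the energy lower bound over an n-point grid (default 50
points over [−25, 0]) and classify the output *dependent* when the
response range exceeds 1e−6.

## Synthetic data and what it does not show

The toy generator emulates the architecture of TLR-type
reconstructions: per-receptor ligand/exchange/binding, an ATP-coupled
cascade with OR-isozyme steps and AND-complex steps (every third step),
demand outputs in the nucleus, optional GTP coupling, planted
extracellular dead-ends, and internal two-cycles. Stoichiometric
coefficients stay in {1, 2} so expected yields are exact rationals and
hand-checkable. Ground truth (reachability, per-output essential genes,
yields) is recorded during construction and cross-checked against the
LP engine.

Expression generation is deliberately idealized: at zero noise, absent
genes get detection p = 1 and present genes p = 0 on every sample, so
any cutoff in (0, 1) recovers the planted truth exactly — that is what
makes exact-recovery tests meaningful. Real microarray data have
correlated probes, intensity-dependent detection probabilities, and
batch structure that this generator does not model; passing recovery
tests therefore validates the *calling and tailoring logic*, not the
statistical robustness of any particular cutoff on real arrays. The
same caveat applies to the differential-expression generator (clean
separation between regulated and null probes).

The packaged `miniTLR` fixture (28 compounds, 36 reactions, 14 genes)
is small enough that every expectation — output capability per
stimulation, sensitivity-curve points, blocked and dead-end sets,
sub-network counts, the co-stimulation-only IRF output — was verified
two ways: by hand from the stoichiometry and by an independent solver
stack (cobrapy/GLPK, `scripts/minitlr_oracle.py`), whose output is the
committed expectations file. The main implementation must reproduce
that file exactly.

## Problem sizes

Default test and acceptance runs use toy networks of 2–4 receptors with
cascade depth 2–4 (tens of reactions), 30 random networks of ≤ 6
reactions for vertex-enumeration cross-checks (the brute-force oracle
is exponential, 3ⁿ patterns), 200 random GPR trees of ≤ 10 leaves for
truth-table checks, and 20 seeded tailoring-recovery instances. These
sizes keep every brute-force oracle exact while exercising all code
paths; the toolkit itself handles models with hundreds of reactions
without special treatment (FVA cost: two LPs per reaction).

## Known limitations

- L1 rather than L2 parsimony (see above); alternative-optima flux
  values are not unique.
- Dead-end detection is structural; it will not flag stoichiometric
  inconsistencies that only an LP reveals (those appear as blocked
  reactions instead).
- SBML support is export plus basic import (species, reactions, bounds,
  FBC gene associations); the TSV dialect is canonical.
- Gene-index enrichment, probe-level preprocessing (detection p-values,
  FDR), and protein-evidence lookups are out of scope: the package
  consumes their outputs.
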