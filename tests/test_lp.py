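"""FBA / min-norm FBA / FVA / robustness against independent references."""

import numpy as np
import pytest

from sigflux.bruteforce import vertex_fva
from sigflux.core import Compound, Model, Reaction, UNBOUNDED
from sigflux.lp import fba, fba_min_norm, fva, robustness_scan
from sigflux.synthetic import generate_random_network
from tests.conftest import chain_model


def test_fba_chain_conservation(chain):
    sol = fba(chain, "DM_B", "max")
    assert sol.ok
    assert sol.objective_value == pytest.approx(1.0)
    assert sol.fluxes["EX_A"] == pytest.approx(-1.0)


def test_fba_closed_exchanges_zero(chain):
    closed = chain.copy()
    closed.reactions["EX_A"].lb = 0.0
    sol = fba(closed, "DM_B", "max")
    assert sol.ok and sol.objective_value == pytest.approx(0.0)


def test_fba_steady_state_and_bounds(minitlr):
    sol = fba(minitlr, "DM_NFKB[n]", "max")
    S, _, rids = minitlr.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in rids])
    assert np.max(np.abs(S @ v)) < 1e-6
    lb, ub = minitlr.bounds_arrays()
    assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)


def test_fba_infeasible_status():
    m = Model("infeasible")
    m.add_compound(Compound("A[c]", "A", "c", "metabolite"))
    # forced import with no consumer
    m.add_reaction(Reaction("EX_A", {"A[c]": -1.0}, -2.0, -1.0, rclass="exchange"))
    sol = fba(m, "EX_A", "max")
    assert sol.status == "infeasible" and sol.fluxes == {}


def _parallel_path_model():
    """Two redundant routes A -> B; min-norm should use only one."""
    m = Model("parallel")
    for cid in ("A[c]", "B[c]", "M[c]"):
        m.add_compound(Compound(cid, cid, "c", "metabolite"))
    m.add_reaction(Reaction("EX_A", {"A[c]": -1.0}, -1.0, 0.0, rclass="exchange"))
    m.add_reaction(Reaction("DIRECT", {"A[c]": -1.0, "B[c]": 1.0}))
    m.add_reaction(Reaction("VIA1", {"A[c]": -1.0, "M[c]": 1.0}))
    m.add_reaction(Reaction("VIA2", {"M[c]": -1.0, "B[c]": 1.0}))
    m.add_reaction(Reaction("DM_B", {"B[c]": -1.0}, rclass="demand"))
    return m


def test_min_norm_prefers_short_path():
    m = _parallel_path_model()
    sol = fba_min_norm(m, "DM_B", "max")
    assert sol.objective_value == pytest.approx(1.0)
    # 1-step route (total |v| = 3) beats the 2-step route (total 4)
    assert sol.fluxes["DIRECT"] == pytest.approx(1.0, abs=1e-6)
    assert sol.fluxes["VIA1"] == pytest.approx(0.0, abs=1e-6)


def test_min_norm_matches_fba_on_loop_free_chain(chain):
    a, b = fba(chain, "DM_B"), fba_min_norm(chain, "DM_B")
    for rid in chain.reactions:
        assert a.fluxes[rid] == pytest.approx(b.fluxes[rid], abs=1e-6)


def test_min_norm_silences_pure_loop(minitlr):
    base = minitlr.copy()
    for rid in ("EX_ligA[e]", "EX_ligB[e]", "EX_ligC[e]", "EX_atp[c]", "EX_gtp[c]"):
        base.reactions[rid].lb = 0.0
        base.reactions[rid].ub = 0.0
    sol = fba_min_norm(base, "DM_NFKB[n]", "max")
    assert sol.fluxes["LOOP_F"] == pytest.approx(0.0, abs=1e-6)
    assert sol.fluxes["LOOP_R"] == pytest.approx(0.0, abs=1e-6)


def test_fva_chain_and_blocked(chain):
    res = fva(chain)
    assert res["DM_B"] == pytest.approx((0.0, 1.0))
    dead = chain.copy()
    dead.add_compound(Compound("C[c]", "C", "c", "metabolite"))
    dead.add_reaction(Reaction("R_DEAD", {"B[c]": -1.0, "C[c]": 1.0}))
    res = fva(dead)
    assert res["R_DEAD"] == pytest.approx((0.0, 0.0))
    assert res.blocked() == {"R_DEAD"}


def test_fva_loop_range_with_closed_exchanges(minitlr):
    closed = minitlr.copy()
    for r in closed.reactions.values():
        if r.rclass == "exchange":
            r.lb, r.ub = 0.0, 0.0
    res = fva(closed, ["LOOP_F", "LOOP_R"])
    # steady state does not constrain an internal 2-cycle; bounds do
    assert res["LOOP_F"] == pytest.approx((0.0, 10.0))
    assert res["LOOP_R"] == pytest.approx((0.0, 10.0))


def test_fva_max_equals_fba_max(minitlr):
    res = fva(minitlr, ["DM_NFKB[n]", "DM_ROS[v]"])
    for rid in ("DM_NFKB[n]", "DM_ROS[v]"):
        assert res.maximum(rid) == pytest.approx(
            fba(minitlr, rid, "max").objective_value, abs=1e-6)


def test_fva_matches_vertex_enumeration_oracle(rng):
    """LP FVA agrees with brute-force vertex enumeration on random nets."""
    for _ in range(10):
        model = generate_random_network(rng)
        oracle = vertex_fva(model)
        res = fva(model)
        for rid, (lo, hi) in oracle.items():
            assert res.minimum(rid) == pytest.approx(lo, abs=1e-6)
            assert res.maximum(rid) == pytest.approx(hi, abs=1e-6)


def test_fva_interval_grows_when_bounds_relax(rng):
    """Relaxing any bound never shrinks an FVA interval."""
    model = generate_random_network(rng)
    before = fva(model)
    relaxed = model.copy()
    rid0 = next(iter(relaxed.reactions))
    relaxed.reactions[rid0].lb -= 5.0
    relaxed.reactions[rid0].ub += 5.0
    after = fva(relaxed)
    for rid in model.reactions:
        assert after.minimum(rid) <= before.minimum(rid) + 1e-6
        assert after.maximum(rid) >= before.maximum(rid) - 1e-6


def test_robustness_scan_grid_and_monotonicity(chain):
    curve = robustness_scan(chain, "EX_A", "DM_B", n_points=50, lb_range=(-25, 0))
    assert len(curve.control_values) == 50
    assert np.all(np.diff(curve.control_values) > 0)
    # maximizing objective: response non-increasing as lb tightens toward 0
    assert np.all(np.diff(curve.responses) <= 1e-9)
    # the scan overrides EX_A's own lb: supply -g flows straight through
    assert curve.responses[0] == pytest.approx(25.0)
    assert curve.responses[-1] == pytest.approx(0.0)


def test_robustness_scan_restores_model(chain):
    before = (chain.reactions["EX_A"].lb, chain.reactions["EX_A"].ub)
    robustness_scan(chain, "EX_A", "DM_B", n_points=5)
    assert (chain.reactions["EX_A"].lb, chain.reactions["EX_A"].ub) == before


def test_robustness_flat_for_unrelated_control(minitlr):
    from sigflux.iosim import configure_io
    from sigflux.synthetic import mini_tlr_io
    pairs, _ = mini_tlr_io()
    cfg = configure_io(minitlr, pairs[0])
    curve = robustness_scan(cfg, "EX_gtp[c]", "DM_NFKB[n]", n_points=8)
    assert curve.classify() == "independent"


def test_fva_matches_cobrapy(rng):
    """Dual-route check: our scipy engine vs cobrapy/GLPK on random nets."""
    import cobra
    from cobra.flux_analysis import flux_variability_analysis

    for _ in range(5):
        model = generate_random_network(rng)
        cm = cobra.Model(model.id)
        mets = {cid: cobra.Metabolite(cid) for cid in model.compounds}
        rxns = []
        for rid, r in model.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = r.lb, r.ub
            rxns.append(cr)
        cm.add_reactions(rxns)
        for cr, r in zip(rxns, model.reactions.values()):
            cr.add_metabolites({mets[c]: k for c, k in r.stoichiometry.items()})
        frame = flux_variability_analysis(cm, fraction_of_optimum=0.0)
        ours = fva(model)
        for rid in model.reactions:
            assert ours.minimum(rid) == pytest.approx(frame.loc[rid, "minimum"], abs=1e-6)
            assert ours.maximum(rid) == pytest.approx(frame.loc[rid, "maximum"], abs=1e-6)
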