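"""Presence calling, tailoring, DE calling, fold-change bounds, gap repair."""

import numpy as np
import pandas as pd
import pytest

from sigflux.contextualize import (apply_fold_change_bounds,
                                   call_differential_expression,
                                   condition_tailor, diagnose_io_gaps,
                                   presence_calls, reaction_fold_changes,
                                   tailor_model, test_gene_reintroduction,
                                   RegulationSet)
from sigflux.core import genes_of
from sigflux.iosim import IOPair, configure_io
from sigflux.lp import fba_min_norm, fva
from sigflux.synthetic import (ToyNetworkConfig, generate_expression_data,
                               generate_toy_network, mini_tlr_io)


def _expr(rows):
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "sample_id",
                                       "group", "detection_p", "intensity"])


def test_presence_single_probe_detected():
    data = _expr([(f"p1", "g1", s, "control", 0.001, 100.0)
                  for s in ("c0", "c1", "c2")])
    assert presence_calls(data, cutoff=0.02) == {"g1": True}


def test_presence_follows_high_intensity_probe():
    """With two probes, the call tracks the brighter probe in controls."""
    rows = []
    for s in ("c0", "c1"):
        rows.append(("p_hi", "g1", s, "control", 0.9, 1000.0))  # bright, absent
        rows.append(("p_lo", "g1", s, "control", 0.001, 10.0))  # dim, present
    assert presence_calls(_expr(rows), cutoff=0.02) == {"g1": False}


def test_presence_majority_vs_all():
    rows = [("p1", "g1", "c0", "control", 0.001, 5.0),
            ("p1", "g1", "c1", "control", 0.001, 5.0),
            ("p1", "g1", "c2", "control", 0.5, 5.0)]
    data = _expr(rows)
    assert presence_calls(data, 0.02, aggregation="majority")["g1"] is True
    assert presence_calls(data, 0.02, aggregation="all")["g1"] is False
    assert presence_calls(data, 0.02, aggregation="any")["g1"] is True


def test_presence_recovers_planted_truth():
    model, _ = generate_toy_network(ToyNetworkConfig(seed=5))
    data, absent = generate_expression_data(model, absent_fraction=0.3,
                                            noise=0.0, seed=5)
    for cutoff in (0.01, 0.02, 0.5, 0.99):
        calls = presence_calls(data, cutoff)
        assert {g for g, p in calls.items() if not p} == absent


def test_tailor_all_present_disables_nothing(minitlr):
    result = tailor_model(minitlr, {g: True for g in genes_of(minitlr)},
                          compute_flux_stats=False)
    assert result.disabled_reactions == set() and result.absent_genes == set()


def test_tailor_isoform_rule(minitlr):
    # one adaptor isoform absent: reactions stay active
    one = tailor_model(minitlr, {"201": False}, compute_flux_stats=False)
    assert "ADAPT_A" not in one.disabled_reactions
    both = tailor_model(minitlr, {"201": False, "202": False},
                        compute_flux_stats=False)
    assert {"ADAPT_A", "ADAPT_B", "ADAPT_C"} <= both.disabled_reactions
    # AND complex: one subunit suffices to disable
    sub = tailor_model(minitlr, {"301": False}, compute_flux_stats=False)
    assert {"KIN_A", "KIN_B", "KIN_C"} <= sub.disabled_reactions


def test_tailor_stats_schema(minitlr):
    result = tailor_model(minitlr, {"201": False, "202": False})
    assert result.stats["n_deleted_genes"] == 2
    assert result.stats["n_constrained_reactions"] == len(result.disabled_reactions)
    assert result.stats["n_blocked"] >= len(result.disabled_reactions)
    assert result.stats["n_dead_ends"] >= 2  # planted ones persist


def test_tailoring_monotone_and_idempotent(minitlr):
    small = tailor_model(minitlr, {"201": False}, compute_flux_stats=False)
    large = tailor_model(minitlr, {"201": False, "202": False, "501": False},
                         compute_flux_stats=False)
    assert small.disabled_reactions <= large.disabled_reactions
    again = tailor_model(large.tailored, {"201": False, "202": False, "501": False},
                         compute_flux_stats=False)
    assert again.disabled_reactions == large.disabled_reactions


def test_condition_tailor_never_readds(minitlr):
    base = tailor_model(minitlr, {"103": False}, compute_flux_stats=False)
    # condition says 103 present again and 102 newly absent
    cond = condition_tailor(base, {"103": True, "102": False},
                            compute_flux_stats=False)
    assert "103" in cond.absent_genes            # stays excluded
    assert "RECC_BIND" in cond.disabled_reactions
    assert "RECB_BIND" in cond.disabled_reactions
    same = condition_tailor(base, {"103": False}, compute_flux_stats=False)
    assert same.disabled_reactions == base.disabled_reactions


def test_condition_tailor_counts_new_losses(minitlr):
    base = tailor_model(minitlr, {}, compute_flux_stats=False)
    cond = condition_tailor(base, {"501": False, "601": False},
                            compute_flux_stats=False)
    assert cond.disabled_reactions == {"NFKB_ACT", "ROS_SYN"}


def _de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "probe_id", "log2_fc", "fdr_p"])


def test_de_calling_basic_and_fraction():
    table = _de([("g1", "p1", np.log2(3), 0.01), ("g1", "p2", np.log2(3), 0.01),
                 ("g2", "p1", 1.2, 0.01), ("g2", "p2", 0.1, 0.9),
                 ("g3", "p1", 2.0, 0.01), ("g3", "p2", 0.0, 0.9), ("g3", "p3", 0.0, 0.9)])
    reg = call_differential_expression(table)
    assert reg.up["g1"] == pytest.approx(3.0)
    assert "g2" in reg.up                      # 1 of 2 = 50% >= 50%
    assert reg.subthreshold == {"g3"}          # 1 of 3 < 50%


def test_de_mixed_direction_warns():
    table = _de([("g1", "p1", 1.5, 0.01), ("g1", "p2", -1.5, 0.01)])
    with pytest.warns(UserWarning, match="both directions"):
        reg = call_differential_expression(table)
    assert reg.subthreshold == {"g1"}


def test_de_down_regulation_magnitude():
    table = _de([("g1", "p1", -2.0, 0.01)])
    reg = call_differential_expression(table)
    assert reg.down["g1"] == pytest.approx(4.0)


def test_reaction_fold_changes_mean_rule(minitlr):
    reg = RegulationSet(up={"201": 2.0, "202": 6.0, "501": 3.0})
    rfc = reaction_fold_changes(minitlr, reg)
    assert rfc.up["ADAPT_A"] == pytest.approx(4.0)      # mean(2, 6)
    assert rfc.up["NFKB_ACT"] == pytest.approx(3.0)
    assert rfc.reference_up == pytest.approx(6.0)
    assert rfc.down == {}


def test_reaction_fold_changes_mixed_excluded(minitlr):
    reg = RegulationSet(up={"201": 2.0}, down={"202": 3.0})
    with pytest.warns(UserWarning, match="excluded"):
        rfc = reaction_fold_changes(minitlr, reg)
    assert "ADAPT_A" not in rfc.up and "ADAPT_A" not in rfc.down


def _configured_minitlr(minitlr):
    pairs, _ = mini_tlr_io()
    return configure_io(minitlr, pairs[0], "quantitative")


def test_apply_fold_change_full_enforcement(minitlr):
    cfg = _configured_minitlr(minitlr)
    ref = fba_min_norm(cfg, "DM_NFKB[n]", "max")
    assert ref.fluxes["NFKB_ACT"] == pytest.approx(1.0, abs=1e-6)
    rfc_up = reaction_fold_changes(cfg, RegulationSet(up={"501": 4.0}))
    adjusted = apply_fold_change_bounds(cfg, rfc_up, ref)
    # FCrxn == FC-up: reference flux fully enforced as minimum
    res = fva(adjusted, ["NFKB_ACT"])
    assert res.minimum("NFKB_ACT") == pytest.approx(1.0, abs=1e-6)


def test_apply_fold_change_full_suppression(minitlr):
    cfg = _configured_minitlr(minitlr)
    ref = fba_min_norm(cfg, "DM_NFKB[n]", "max")
    rfc = reaction_fold_changes(cfg, RegulationSet(up={"999": 2.0},
                                                   down={"403": 5.0}))
    adjusted = apply_fold_change_bounds(cfg, rfc, ref)
    for rid in ("CASC_A", "CASC_B", "CASC_C"):
        assert adjusted.reactions[rid].ub == pytest.approx(0.0)


def test_apply_fold_change_zero_reference_untouched(minitlr):
    cfg = _configured_minitlr(minitlr)
    ref = fba_min_norm(cfg, "DM_NFKB[n]", "max")
    assert abs(ref.fluxes["CREB_ACT"]) < 1e-9
    rfc = reaction_fold_changes(cfg, RegulationSet(up={"402": 4.0}))
    adjusted = apply_fold_change_bounds(cfg, rfc, ref)
    r = adjusted.reactions["CREB_ACT"]
    assert (r.lb, r.ub) == (cfg.reactions["CREB_ACT"].lb,
                            cfg.reactions["CREB_ACT"].ub)


def test_apply_fold_change_shrinks_feasible_set(minitlr):
    cfg = _configured_minitlr(minitlr)
    ref = fba_min_norm(cfg, "DM_NFKB[n]", "max")
    before = fva(cfg, ["DM_NFKB[n]", "DM_CREB[n]"])
    rfc = reaction_fold_changes(cfg, RegulationSet(up={"501": 4.0}))
    after = fva(apply_fold_change_bounds(cfg, rfc, ref),
                ["DM_NFKB[n]", "DM_CREB[n]"])
    for rid in ("DM_NFKB[n]", "DM_CREB[n]"):
        assert after.maximum(rid) <= before.maximum(rid) + 1e-6


def test_gap_diagnosis_and_reintroduction(minitlr):
    pairs, _ = mini_tlr_io()
    io = IOPair("RECA", ("EX_ligA[e]",), ("RECA_BIND",), output_rxn="DM_NFKB[n]")
    draft = tailor_model(minitlr, {"501": False}, compute_flux_stats=False)
    diag = diagnose_io_gaps(minitlr, draft, io)
    assert "NFKB_ACT" in diag["missing_reactions"]
    assert diag["candidate_genes"] == {"501"}

    healthy = tailor_model(minitlr, {}, compute_flux_stats=False)
    assert diagnose_io_gaps(minitlr, healthy, io) == \
        {"missing_reactions": set(), "candidate_genes": set()}

    table = test_gene_reintroduction(draft, minitlr, {"501"},
                                     ["DM_NFKB[n]"], io=io)
    assert table["501"]["DM_NFKB[n]"] == pytest.approx(1.0, abs=1e-6)


def test_reintroducing_redundant_isoform_changes_nothing(minitlr):
    pairs, _ = mini_tlr_io()
    io = IOPair("RECA", ("EX_ligA[e]",), ("RECA_BIND",), output_rxn="DM_NFKB[n]")
    draft = tailor_model(minitlr, {"202": False}, compute_flux_stats=False)
    assert draft.disabled_reactions == set()   # 201 still carries the adaptor
    table = test_gene_reintroduction(draft, minitlr, {"202"}, ["DM_NFKB[n]"], io=io)
    cfg = configure_io(minitlr, io)
    assert table["202"]["DM_NFKB[n]"] == pytest.approx(
        fva(cfg, ["DM_NFKB[n]"]).maximum("DM_NFKB[n]"), abs=1e-6)


def test_gap_diagnosis_broken_reference_errors(minitlr):
    io = IOPair("RECA", ("EX_ligA[e]",), ("RECA_BIND",), output_rxn="DM_IRF[n]")
    draft = tailor_model(minitlr, {}, compute_flux_stats=False)
    with pytest.raises(RuntimeError, match="reference"):
        # single stimulation cannot force the co-stimulation output
        diagnose_io_gaps(minitlr, draft, io)
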