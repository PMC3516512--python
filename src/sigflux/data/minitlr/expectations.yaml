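# Brute-force expectations for the miniTLR fixture.
# Generated by scripts/minitlr_oracle.py (cobrapy/GLPK);
# do not edit by hand — rerun the script instead.
blocked_raw:
- ORPH_BIND
- SHED_A
costimulation:
  irf_max_costim: 1.0
  irf_max_single: 0.0
dead_ends:
- orphL[e]
- shedA[e]
loop_fva_raw:
  LOOP_F:
  - 0.0
  - 10.0
  LOOP_R:
  - 0.0
  - 10.0
output_fva:
  RECA:
    DM_AP1[n]:
    - 0.0
    - 0.0
    DM_CREB[n]:
    - 0.0
    - 1.0
    DM_IRF[n]:
    - 0.0
    - 0.0
    DM_NFKB[n]:
    - 0.0
    - 1.0
    DM_ROS[v]:
    - 0.0
    - 0.0
  RECA+RECC:
    DM_AP1[n]:
    - 0.0
    - 0.0
    DM_CREB[n]:
    - 0.0
    - 1.0
    DM_IRF[n]:
    - 0.0
    - 1.0
    DM_NFKB[n]:
    - 0.0
    - 1.0
    DM_ROS[v]:
    - 0.0
    - 0.0
  RECB:
    DM_AP1[n]:
    - 0.0
    - 1.0
    DM_CREB[n]:
    - 0.0
    - 0.0
    DM_IRF[n]:
    - 0.0
    - 0.0
    DM_NFKB[n]:
    - 0.0
    - 0.0
    DM_ROS[v]:
    - 0.0
    - 1.0
  RECC:
    DM_AP1[n]:
    - 0.0
    - 0.0
    DM_CREB[n]:
    - 0.0
    - 0.0
    DM_IRF[n]:
    - 0.0
    - 0.0
    DM_NFKB[n]:
    - 0.0
    - 0.0
    DM_ROS[v]:
    - 0.0
    - 0.0
  baseline:
    DM_AP1[n]:
    - 0.0
    - 0.0
    DM_CREB[n]:
    - 0.0
    - 0.0
    DM_IRF[n]:
    - 0.0
    - 0.0
    DM_NFKB[n]:
    - 0.0
    - 0.0
    DM_ROS[v]:
    - 0.0
    - 0.0
sensitivity_curves:
- control: EX_atp[c]
  grid:
  - -25.0
  - -20.0
  - -15.0
  - -10.0
  - -5.0
  - 0.0
  lb_range:
  - -25.0
  - 0.0
  n_points: 6
  output: DM_NFKB[n]
  pair: RECA
  responses:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 0.0
- control: EX_gtp[c]
  grid:
  - -25.0
  - -20.0
  - -15.0
  - -10.0
  - -5.0
  - 0.0
  lb_range:
  - -25.0
  - 0.0
  n_points: 6
  output: DM_NFKB[n]
  pair: RECA
  responses:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- control: EX_atp[c]
  grid:
  - -3.0
  - -2.5
  - -2.0
  - -1.5
  - -1.0
  - -0.5
  - 0.0
  lb_range:
  - -3.0
  - 0.0
  n_points: 7
  output: DM_NFKB[n]
  pair: RECA
  responses:
  - 1.0
  - 0.833333
  - 0.666667
  - 0.5
  - 0.333333
  - 0.166667
  - 0.0
- control: EX_gtp[c]
  grid:
  - -25.0
  - -20.0
  - -15.0
  - -10.0
  - -5.0
  - 0.0
  lb_range:
  - -25.0
  - 0.0
  n_points: 6
  output: DM_ROS[v]
  pair: RECB
  responses:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 0.0
- control: EX_atp[c]
  grid:
  - -2.0
  - -1.666667
  - -1.333333
  - -1.0
  - -0.666667
  - -0.333333
  - 0.0
  lb_range:
  - -2.0
  - 0.0
  n_points: 7
  output: DM_ROS[v]
  pair: RECB
  responses:
  - 1.0
  - 0.833333
  - 0.666667
  - 0.5
  - 0.333333
  - 0.166667
  - 0.0
- control: EX_atp[c]
  grid:
  - -6.0
  - -5.0
  - -4.0
  - -3.0
  - -2.0
  - -1.0
  - 0.0
  lb_range:
  - -6.0
  - 0.0
  n_points: 7
  output: DM_IRF[n]
  pair: RECA+RECC
  responses:
  - 1.0
  - 0.833333
  - 0.666667
  - 0.5
  - 0.333333
  - 0.166667
  - 0.0
subnetworks:
  adaptor_isozymes:
    genes:
    - '201'
    - '202'
    n_compounds: 8
    n_reactions: 3
    reaction_ids:
    - ADAPT_A
    - ADAPT_B
    - ADAPT_C
  cascade_isozymes:
    genes:
    - '401'
    - '402'
    - '403'
    n_compounds: 9
    n_reactions: 4
    reaction_ids:
    - CASC_A
    - CASC_B
    - CASC_C
    - CREB_ACT
  receptor_A:
    genes:
    - '101'
    n_compounds: 2
    n_reactions: 1
    reaction_ids:
    - RECA_BIND
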