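# Reference I/O configuration for the human TLR signaling network
# (ihsTLRv2 reaction naming).  Thirteen receptor stimulation
# configurations paired against nine output reactions give the full set
# of 117 input/output relationships.  IRF7 output requires two-receptor
# co-stimulation; the TLR4+TLR8 entry encodes that protocol.
inputs:
  - input_id: NOD1
    exchange: ["EX_26dap-LL[e]"]
    binding: ["NOD1P_BIND"]
  - input_id: TLR2
    exchange: ["EX_ALPS[e]"]
    binding: ["TLR2/L-D_BIND"]
  - input_id: TLR2b
    exchange: ["EX_HSP70_HS[e]"]
    binding: ["TLR2/L_BIND"]
  - input_id: TLR4
    exchange: ["EX_LPS_HS[e]"]
    binding: ["TLR4/L_MD2_BIND"]
  - input_id: TLR5
    exchange: ["EX_FLGN[e]"]
    binding: ["TLR5_BIND"]
  - input_id: TLR1/2
    exchange: ["EX_TCLDLPP[e]"]
    binding: ["TLR1/2_BIND"]
  - input_id: TLR7
    exchange: ["EX_BPM[e]"]
    binding: ["TLR7_BIND"]
  - input_id: TLR8
    exchange: ["EX_SSRNA[e]"]
    binding: ["TLR8_BIND"]
  - input_id: TLR9
    exchange: ["EX_UMLCPGD[e]"]
    binding: ["TLR9_BIND"]
  - input_id: TLR9II
    exchange: ["EX_UMLCPGD[e]"]
    binding: ["TLR9_BINDII"]
  - input_id: NOD2
    exchange: ["EX_MRDP[e]"]
    binding: ["NOD2P_BIND"]
  - input_id: IL1R1
    exchange: ["EX_IL1R1_LIG[e]"]
    binding: ["IL1R1_BIND"]
  - input_id: TLR4+TLR8
    exchange: ["EX_LPS_HS[e]"]
    binding: ["TLR4/L_MD2_BIND"]
    co_stimulation:
      input_id: TLR8
      exchange: ["EX_SSRNA[e]"]
      binding: ["TLR8_BIND"]
outputs:
  - "DM_PHOX_GTP-3P[v]"
  - "DM_PHOX_GTP-8P[v]"
  - "DM_ISRE_IRF3[n]"
  - "DM_ISRE_IRF7[n]"
  - "CREB_CRE_BIND"
  - "AP1_FOS_JUN_BIND"
  - "AP1_JUN_BIND"
  - "NFKB_IKBA_DISS"
  - "NFKB_IKBB_DISS"
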