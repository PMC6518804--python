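# Family-membership rule table, evaluated in priority order: the first rule
# whose required domains are all present (or, for required_any, at least one)
# and whose forbidden domains are all absent assigns the family.  Canonicity
# within a family (phosphoacceptor residue, kinase motif boxes, receiver and
# transactivation domains) is judged by the classifier itself.
rules:
  - family: CHK          # CHASE-domain cytokinin receptor
    required: [CHASE]
  - family: ETR          # ethylene receptor
    required: [EBD]
    forbidden: [CHASE]
  - family: HK           # non-CHASE histidine kinase
    required_any: [His, HATPase_c]
    forbidden: [CHASE, EBD, Hpt]
  - family: HPT          # histidine phosphotransfer protein
    required: [Hpt]
  - family: clock-RR     # pseudo response regulator (receiver + CCT)
    required: [Rec, CCT]
  - family: RRB          # Type-B response regulator (receiver + Myb)
    required: [Rec, Myb]
  - family: RRB          # Myb-less receiver + transactivation, groups with RRBs
    required: [Rec, C-ter]
    forbidden: [Myb]
    variant: Myb-less
  - family: RRA          # receiver-only (refined to RRC/RRB-like by
    required: [Rec]      # nearest-reference assignment when sequences exist)
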