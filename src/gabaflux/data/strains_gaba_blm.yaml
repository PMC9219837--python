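# In-silico analogs of the GABA-1..6 / BLM-1..3 strain series.
# Edits are cumulative along the GABA line; BLM strains add the
# acetyl-CoA-dependent butyrolactam branch on late GABA backgrounds.
# "overexpress" fixes the reaction flux at factor x its wild-type pFBA flux.
strains:
  - label: GABA-1
    description: base GABA producer (heterologous GAD route, bi-cistronic cassette analog)
    edits: []
  - label: GABA-2
    description: aconitase upregulation (P_tuf-acn analog)
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
  - label: GABA-3
    description: plus isocitrate dehydrogenase upregulation (P_tuf-icd analog)
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
  - label: GABA-4
    description: plus succinyl-CoA synthetase knockout (dsucCD)
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
      - {op: delete, role: SUCOAS, label: dsucCD}
  - label: GABA-5
    description: plus GABA shunt knockout (dgadT dgadD)
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
      - {op: delete, role: SUCOAS, label: dsucCD}
      - {op: delete, role: GABA_SHUNT_T, label: dgadT}
      - {op: delete, role: GABA_SHUNT_D, label: dgadD}
  - label: GABA-6
    description: plus transport rewiring (gadP replaced by potE exporter)
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
      - {op: delete, role: SUCOAS, label: dsucCD}
      - {op: delete, role: GABA_SHUNT_T, label: dgadT}
      - {op: delete, role: GABA_SHUNT_D, label: dgadD}
      - {op: close, role: GABA_UPTAKE, label: dgadP}
      - {op: open, role: GABA_EXPORT, lower: 0.0, upper: 1000.0, label: potE}
  - label: BLM-1
    description: butyrolactam branch (act) on the GABA-4 background
    pathways: [butyrolactam]
    product_rxn: EX_blm_c
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
      - {op: delete, role: SUCOAS, label: dsucCD}
  - label: BLM-2
    description: butyrolactam branch on the GABA-5 background
    pathways: [butyrolactam]
    product_rxn: EX_blm_c
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
      - {op: delete, role: SUCOAS, label: dsucCD}
      - {op: delete, role: GABA_SHUNT_T, label: dgadT}
      - {op: delete, role: GABA_SHUNT_D, label: dgadD}
  - label: BLM-3
    description: butyrolactam branch on the GABA-6 background
    pathways: [butyrolactam]
    product_rxn: EX_blm_c
    edits:
      - {op: overexpress, role: ACN, factor: 2.0, label: P_tuf-acn}
      - {op: overexpress, reaction: ICD, factor: 2.0, label: P_tuf-icd}
      - {op: delete, role: SUCOAS, label: dsucCD}
      - {op: delete, role: GABA_SHUNT_T, label: dgadT}
      - {op: delete, role: GABA_SHUNT_D, label: dgadD}
      - {op: close, role: GABA_UPTAKE, label: dgadP}
      - {op: open, role: GABA_EXPORT, lower: 0.0, upper: 1000.0, label: potE}
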