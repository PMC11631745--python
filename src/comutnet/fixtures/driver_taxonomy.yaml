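# Default driver-group taxonomy for the seven NSCLC driver genes.
# Groups are matched first-to-last; a record matches a group when every
# listed condition holds.  A gene's altered samples matching no rule
# fall into "other <gene> alteration".
genes:
  ALK:
    groups:
      - name: EML4-ALK fusion
        alt_class: [fusion]
        variant_contains: EML4
      - name: other ALK fusion
        alt_class: [fusion]
      - name: other ALK alteration
  EGFR:
    groups:
      - name: therapy-associated EGFR
        tier: [guideline_indicated]
      - name: other EGFR alteration
  MET:
    groups:
      - name: MET exon 14 skipping
        alt_class: [exon_skip]
      - name: MET amplification
        alt_class: [cnv_gain]
      - name: other MET alteration
  BRAF:
    groups:
      - name: BRAF V600E
        variant_equals: [V600E, p.V600E]
      - name: other BRAF alteration
  ROS1:
    groups:
      - name: ROS1 fusion
        alt_class: [fusion]
      - name: other ROS1 alteration
  ERBB2:
    groups:
      - name: ERBB2 Y772-A775dup
        variant_contains: Y772
      - name: ERBB2 amplification
        alt_class: [cnv_gain]
      - name: other ERBB2 alteration
  KRAS:
    groups:
      - name: KRAS G12C
        variant_equals: [G12C, p.G12C]
      - name: KRAS G12D
        variant_equals: [G12D, p.G12D]
      - name: KRAS G12V
        variant_equals: [G12V, p.G12V]
      - name: KRAS G12A
        variant_equals: [G12A, p.G12A]
      - name: KRAS G13C
        variant_equals: [G13C, p.G13C]
      - name: KRAS G13D
        variant_equals: [G13D, p.G13D]
      - name: KRAS Q61H
        variant_equals: [Q61H, p.Q61H]
      - name: other KRAS alteration
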