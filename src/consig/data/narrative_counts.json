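{
  "comment": "Published counts from the source study, kept as reference inputs for fixtures and generator defaults. The rat-mouse pairwise overlap is reported inconsistently (151 in the text, 150 in the gene-set table); both values are recorded and neither is used downstream.",
  "species_set_sizes": {"human": 2386, "mouse": 883, "rat": 616},
  "pairwise_overlaps": {
    "human_mouse": 378,
    "human_rat": 219,
    "mouse_rat_text": 151,
    "mouse_rat_table": 150
  },
  "conserved_core_size": 96,
  "supplemental_set_size": 319,
  "supplemental_conserved_genes": ["GJA1", "CCN1", "H2AX", "IL10", "WRN", "HSP90AA1"],
  "conserved_total": 102,
  "de_union_size": 2161,
  "subtype_set_sizes": {
    "BL1": {"up": 215, "down": 251},
    "BL2": {"up": 154, "down": 127},
    "M": {"up": 247, "down": 446},
    "LAR": {"up": 805, "down": 382}
  },
  "resistant_subtypes": ["LAR", "M"],
  "sensitive_subtypes": ["BL1", "BL2"],
  "overlap_gene_count": 20,
  "up_in_any": 16,
  "down_in_any": 11,
  "signature_size": 13,
  "death_flagged": 15,
  "supplemental_de_count": 1,
  "exclusivity_sizes": {"only-LAR": 7, "only-M": 3, "LAR+M": 3},
  "subtype_overlap_counts": {
    "BL1": {"up": 2, "down": 5},
    "BL2": {"up": 4, "down": 0},
    "M": {"up": 5, "down": 3},
    "LAR": {"up": 8, "down": 3}
  }
}
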