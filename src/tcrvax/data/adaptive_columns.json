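{
  "v_gene": ["v_resolved", "vGeneName", "v_gene", "vMaxResolved"],
  "cdr3_aa": ["amino_acid", "aminoAcid", "cdr3_amino_acid"],
  "count": ["templates", "count (templates/reads)", "count", "reads"],
  "frame": ["frame_type", "frameType", "sequenceStatus"]
}
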