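# Microbial dysbiosis index taxon lists (editable).
#
# Names are matched against feature ids first and then as substrings of the
# Greengenes lineage strings, so family/order names pick up all member
# features.  The default lists follow the published MDI convention for
# ileal Crohn's disease: taxa increased in new-onset disease versus taxa
# depleted in disease.
disease_taxa:
  - Enterobacteriaceae
  - Pasteurellaceae
  - Veillonellaceae
  - Fusobacteriaceae
  - Neisseriaceae
  - Gemellaceae
health_taxa:
  - Erysipelotrichales
  - Bacteroidales
  - Clostridiales
# pseudocount: null -> half the smallest nonzero relative abundance
pseudocount: null
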