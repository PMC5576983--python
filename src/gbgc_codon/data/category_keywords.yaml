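# Keyword lists mapping gene-set names to broad functional categories.
# A set name matching any keyword (case-insensitive substring) joins the
# category; names matching negation_pattern never join 'proliferation'.
proliferation:
  - chromatin modification
  - chromatin remodeling
  - mitotic cell cycle
  - mRNA metabolic process
  - negative regulation of cell cycle
  - nucleosome assembly
  - translation
differentiation:
  - development
  - differentiation
  - cell adhesion
  - pattern specification
  - multicellular organism growth
  - angiogenesis
negation_pattern: "negative regulation of (cell )?proliferation"
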