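# Default adduct set.  atoms_added / atoms_removed are molecular-formula
# strings; an absent key means the null formula.  |charge| must be 1.
- label: "[M+H]+"
  polarity: positive
  atoms_added: H
  charge: 1
- label: "[M+Na]+"
  polarity: positive
  atoms_added: Na
  charge: 1
- label: "[M+K]+"
  polarity: positive
  atoms_added: K
  charge: 1
- label: "[M-H]-"
  polarity: negative
  atoms_removed: H
  charge: -1
- label: "[M+Cl]-"
  polarity: negative
  atoms_added: Cl
  charge: -1
- label: "[M+HCOO]-"
  polarity: negative
  atoms_added: CHO2
  charge: -1
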