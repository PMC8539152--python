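# Standard combustion enthalpies of the elements, per mole of element atom,
# used to convert a heat of combustion into a heat of formation by Hess's law:
#     dHf(compound) = sum_e n_e * c_e  -  dHc(compound)
# Each value c_e is the formation enthalpy of the element's reference
# combustion product, per atom of the element (CODATA-consistent, 298.15 K).
schema_version: 1
product_convention:
  C: CO2(g)
  H: H2O(l), 1/2 per H atom
  N: N2(g)
  O: O2(g) bookkeeping, zero by definition
  S: SO2(g)
  P: P4O10(s), 1/4 per P atom
  Si: SiO2(s, alpha-quartz)
  B: B2O3(s), 1/2 per B atom
  halogens: >
    unsupported by default: the aqueous HX product convention (HF.nH2O,
    HCl.nH2O) is source-dependent; supply an override table to enable them.
elements:
  C: -393.51
  H: -142.915
  N: 0.0
  O: 0.0
  S: -296.81
  P: -746.0
  Si: -910.7
  B: -636.75
  F: unsupported
  Cl: unsupported
  Br: unsupported
  I: unsupported
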