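# Default ion-specificity rule table for ATP-synthase c subunits.
#
# Positions are 1-based on the packaged synthetic reference c subunit
# (c_subunit_reference_synthetic.fasta).  A query is classified Na_plus when
# every quartet position carries one of its accepted residues; otherwise
# H_plus when the ion-binding carboxylate (E/D) is present; otherwise
# unclassified.  This table is a documented reconstruction of the commonly
# used Na+-binding diagnostic (Q/E/S/T quartet vs. lone carboxylate) and is
# fully user-overridable.
reference: c_subunit_reference_synthetic
carboxylate:
  position: 60
  residues: "ED"
na_quartet:
  27: "Q"
  60: "E"
  61: "S"
  62: "T"
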