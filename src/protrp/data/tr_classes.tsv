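# TR class definitions, one per line: name<TAB>expression
#
# Expression mini-syntax:
#   P          literal residue
#   [ST]       any of the listed residues
#   [^P]       any residue except those listed
#   .          any residue
#   P{3,4}     bounded repetition of the preceding atom (also {m})
#   [AP|ST]    multi-motif alternation: motif AP or motif ST
#   ... and not [HY]   match vetoed if H or Y occurs anywhere in the motif
#
# Patterns are matched phase-insensitively against TR consensus
# sequences.  The tp3a entry is the published expression for the
# T/S-P3-A arabinogalactan-protein repeat class; further class
# definitions can be appended in the same format.
tp3a	[TS]P{3,4}[VA]{1,2}[TS].P and not [HY]
# Synthetic definitions for the planted motif families of the bundled
# generator (extensin-like SPn, PRP-like, PELPK-like, hybrid motifs).
# Non-proline positions of repeat families drift between sequences, so
# each class is keyed on its conserved proline backbone with wildcarded
# spacer residues; classes sharing a backbone prefix may multi-match,
# which the assignment table reports.
syn_ext	[^P]P{4}[^P]{4}
syn_prp	PP[^P]{3}PP[^P]{2}
syn_pelpk	P[^P]{2}P[^P]P[^P]P
syn_hlt	PP[^P]{3}PP[^P]{3}
syn_hpo	PPP[^P]P[^P]{4}P[^P]
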