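# Curated tailoring-enzyme modification rules.
#
# One blank-line-separated block per rule:
#   name: / motif: (SMILES, explicit [H] where actions address hydrogens)
#   enzymes: (profile ids that license the rule) / optional: true|false
# followed by one action per line: disconnect I J | connect I J K |
# remove I | add I FORMULA.  Indices are 1-based motif SMILES atom order.

name: dehydration_ser
motif: OC([H])([H])C([H])(N)C=O
enzymes: PF05147 PF04738 DUF4135
optional: true
disconnect 1 2
remove 1
disconnect 5 6
remove 6
connect 2 5 2

name: dehydration_thr
motif: OC([H])(C)C([H])(N)C=O
enzymes: PF05147 PF04738 DUF4135
optional: true
disconnect 1 2
remove 1
disconnect 5 6
remove 6
connect 2 5 2

name: nterm_dimethylation
motif: [H]N([H])CC=O
enzymes: PF13649 PF08242
optional: true
disconnect 1 2
remove 1
add 2 CH3
disconnect 2 3
remove 3
add 2 CH3

name: lanthionine
motif: [H]SC([H])([H])C(N)C=O.C(=C([H])[H])(N)C=O
enzymes: PF05147 PF04738 DUF4135
optional: true
disconnect 1 2
remove 1
connect 10 11 1
connect 2 11 1
add 10 H

name: macrolactam
motif: [H]N([H])CC=O.[H]OC(=O)C
enzymes: PF00733
optional: true
disconnect 7 8
remove 7
disconnect 8 9
remove 8
disconnect 1 2
remove 1
connect 2 9 1

name: oxidative_decarboxylation
motif: [H]OC(=O)C([H])(N)C([H])([H])S[H]
enzymes: PF02441
optional: true
remove 1
disconnect 3 5
remove 2
remove 4
remove 3
disconnect 8 9
remove 9
connect 5 8 2

name: thiazoline
motif: O=C(C)N([H])C(C=O)C([H])([H])S[H]
enzymes: PF00881 TIGR03604
optional: true
disconnect 12 13
remove 13
connect 2 12 1
disconnect 1 2
remove 1
disconnect 4 5
remove 5
connect 2 4 2
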