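lo,hi,assignment
950,1000,"C-C (protein, collagen)"
1004,1004,phenylalanine
1030,1030,C-H (phenylalanine)
1050,1100,C-C (lipid)
1100,1100,O-P-O (phosphate backbone)
1120,1130,C-C (lipid)
1120,1200,C-C/C-N (protein)
1200,1300,"amide III, a-helix, b-sheet"
1300,1350,"C-H2 (lipid), protein, nucleic acid"
1450,1450,C-H2 (lipid)
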