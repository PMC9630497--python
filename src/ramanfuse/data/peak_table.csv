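position_cm1,direction,assignment,segment
492,-,S-S stretch,plasma
608,-,CH2 twist,plasma
1437,-,CH2 bending in proteins and lipids,plasma
1526,-,C-N stretching Amide II,plasma
1639,+,Amide I C=O stretching vibrations in proteins,plasma
488,-,Glycogen,saliva
543,+,S-S disulfide bridges in cysteine,saliva
679,+,Guanine ring breathing,saliva
746,-,C-S aliphatic stretching Thymine,saliva
814,+,Phosphodiester bands,saliva
837,-,Amino acids sugars and nucleic acids,saliva
915,-,Carbohydrate-related vibrations,saliva
948,+,C-C alpha-helix,saliva
1000,+,Symmetric ring breathing mode of phenylalanine,saliva
1053,-,C-C stretch lipids,saliva
1328,+,Amide III-collagen,saliva
1445,+,CH2 and CH3 deformations in proteins and lipids,saliva
1658,+,Amide I (C=O stretching of proteins)/C=C lipid stretch,saliva
1704,-,Amide I,saliva
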