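# 13 physicochemical attributes, each partitioning the 20 standard amino
# acids into 3 classes (Dubchak-style table, iFeature convention).
# columns: property, class1 name, class1 residues, class2 name, class2
# residues, class3 name, class3 residues
hydrophobicity_PRAM900101	polar	RKEDQN	neutral	GASTPHY	hydrophobic	CLVIMFW
hydrophobicity_ARGP820101	polar	QSTNGDE	neutral	RAHCKMV	hydrophobic	LYPFIW
hydrophobicity_ZIMJ680101	polar	QNGSWTDERA	neutral	HMCKV	hydrophobic	LPFYI
hydrophobicity_PONP930101	polar	KPDESNQT	neutral	GRHA	hydrophobic	YMFWLCVI
hydrophobicity_CASG920101	polar	KDEQPSRNTG	neutral	AHYMLV	hydrophobic	FIWC
hydrophobicity_ENGD860101	polar	RDKENQHYP	neutral	SGTAW	hydrophobic	CVLIMF
hydrophobicity_FASG890101	polar	KERSQD	neutral	NTPG	hydrophobic	AYHWVMFLIC
normwaalsvolume	low	GASTPDC	medium	NVEQIL	high	MHKFRYW
polarity	low	LIFWCMVY	medium	PATGS	high	HQRKNED
polarizability	low	GASDT	medium	CPNVEQIL	high	KMHFRYW
charge	positive	KR	neutral	ANCQGHILMFPSTWYV	negative	DE
secondarystruct	helix	EALMQKRH	strand	VIYCWFT	coil	GNPSD
solventaccess	buried	ALFCGIVW	exposed	RKQEND	intermediate	MSPTHY
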