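>LMWGS_SYN SYNTHETIC low-molecular-weight glutenin subunit stand-in; landmark coordinates follow the published Tri a 36 peptide map (signal 1-20, repetitive domain 34-197, QQQPPFSQQQPPFSQQ at 77-92 and 115-130, SQQQLPPFSQQQSPFSQQQQ at 142-161, Met344-Cys345, Thr354-Thr355); NOT the UniProt B2Y2Q7 sequence
MKTFLVFALLAVAATSAIAQMETSHIPGLERPSQQQPLPPQQSFSQQQQPVLPQQPPFSQ
QQQQPLPQQQIPIVQQQQQPPFSQQQPPFSQQQPILPQQSPFSQQQQLVLPPQQQQQPPF
SQQQPPFSQQQPGFIQPSLQQSQQQLPPFSQQQSPFSQQQQPVLPQQSPFSQQQQPVLSQ
QPPFSQQQQQPILPQQQIIQQQLQQQIFWGIPALLKRYYPSVTSPQQVSYYQGQAQQPGQ
WQQPGQGQQGYYPTSPQQSGQGQQPGKWQEPGQGQQGYYPTSLQQPGQGQQGHYPASLQQ
PGQGQRPWYYPTSPQQSGQGQQSGQGQQGYYPTSLQQTGQGQQMCNVNVPLYRTTTSVPL
GVGY
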