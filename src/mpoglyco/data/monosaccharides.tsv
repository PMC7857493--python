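name	monoisotopic	average
Hex	162.05282	162.1406
HexNAc	203.07937	203.1925
dHex	146.05791	146.1412
NeuAc	291.09542	291.2546
Phospho	79.96633	79.9799
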