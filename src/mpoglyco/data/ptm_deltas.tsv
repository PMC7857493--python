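name	targets	monoisotopic	average	max_copies
oxidation	MW	15.99491	15.9994	27
dioxidation	MW	31.98983	31.9988	27
chlorination	Y	33.96103	34.4451	2
heme_b	-	616.17730	616.4873	1
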