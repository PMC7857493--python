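chain	start	end
signal	1	48
propeptide	49	164
light	165	278
heavy	279	745
mature	165	745
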