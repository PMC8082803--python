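# name=toy_mini unit=weeks
cpg,weight
(Intercept),30.0
cgA,10.0
cgB,-5.0
cgC,2.0
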