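# clock_name=fixture_identity
# transform=identity
# species_scope=any
# tissue_scope=any
# citation=bundled synthetic fixture clock for tests and demos
var,coef
(Intercept),2.5
cg00001,1.25
cg00002,-0.75
cg00003,0.5
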