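# clock_name=fixture_loglog
# transform=loglog_relative_age
# transform_params={"L": 25.0, "g": 0.3}
# species_scope=any
# tissue_scope=any
# citation=bundled synthetic fixture clock for tests and demos
var,coef
(Intercept),-0.5
cg00001,2.0
cg00004,-1.0
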