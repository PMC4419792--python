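# Single-copy family: no duplications, no losses; the expected ancient
# paralog count is 1.
name: "null"
component: Sec31
base_paralog: Sec31
root_length: 500
subst_rate: 1.0
duplications: []
losses: []
rate_multipliers: []
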