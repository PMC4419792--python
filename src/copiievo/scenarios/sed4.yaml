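# A recent duplication of the Sec12 family inside one opisthokont subclade
# (two taxa carry the young Sed4-like paralog); not an ancient paralog.
name: sed4
component: Sec12
base_paralog: Sec12
root_length: 500
subst_rate: 1.0
duplications:
  - edge: Opisthokonta_1
    fraction: 0.5
    name: Sed4
    parent: Sec12
losses: []
rate_multipliers: []
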