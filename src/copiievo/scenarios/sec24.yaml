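# Three pre-LECA Sec24 paralogs; the third lost in opisthokonts and excavates
# (retained in Amoebozoa, Archaeplastida and SAR/CCTH).
name: sec24
component: Sec24
base_paralog: Sec24I
root_length: 500
subst_rate: 1.0
duplications:
  - edge: root
    fraction: 0.3
    name: Sec24II
    parent: Sec24I
  - edge: root
    fraction: 0.6
    name: Sec24III
    parent: Sec24II
losses:
  - paralog: Sec24III
    clade: Opisthokonta
  - paralog: Sec24III
    clade: Excavata
rate_multipliers:
  - clade: Excavata
    factor: 1.5
    stem_only: true
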