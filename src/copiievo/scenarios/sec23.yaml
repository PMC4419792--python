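# An ancient Sec23 duplication predating the archaeplastid lineage: the
# second copy is retained in every supergroup except the Excavata, giving two
# distinct Sec23 clades inside the Archaeplastida.
name: sec23
component: Sec23
base_paralog: Sec23A
root_length: 500
subst_rate: 1.0
duplications:
  - edge: root
    fraction: 0.5
    name: Sec23B
    parent: Sec23A
losses:
  - paralog: Sec23B
    clade: Excavata
rate_multipliers:
  - clade: SAR_CCTH
    factor: 1.8
    stem_only: true
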