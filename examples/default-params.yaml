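# Default circular-MdRQA configuration: single embedding dimension over
# the 2-D (cos psi, sin psi) signal, unit delay, no normalisation or
# z-scoring, radius 1 (recurrence iff circular phase difference <= 60 deg).
emb: 1
delay: 1
norm: none
radius: 1.0
zscore: false
lmin: 2
theiler: 1
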