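# Naive / early differentiation program (editable)
CCR7
SELL
TCF7
LEF1
IL7R
CD27
CD28
BACH2
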