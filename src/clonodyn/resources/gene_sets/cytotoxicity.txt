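# Cytotoxic effector program (editable; replace with your preferred curated set)
GZMA
GZMB
GZMH
GZMK
PRF1
GNLY
NKG7
KLRG1
KLRD1
FGFBP2
CTSW
CST7
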