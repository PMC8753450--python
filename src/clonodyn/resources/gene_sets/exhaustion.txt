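# Exhaustion / chronic-activation program (editable)
PDCD1
HAVCR2
LAG3
CTLA4
TIGIT
TOX
ENTPD1
BATF
CD160
EOMES
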