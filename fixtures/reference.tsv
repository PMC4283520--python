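UPT	-100
R1	100
R2	20
R3	80
EX_P	20
EX_W	80
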