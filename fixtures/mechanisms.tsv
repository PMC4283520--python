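R1	uni-uni	
R2	uni-uni	
R3	uni-uni	
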