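name	LD-SM
model_order	50
channel	C3
channel	C4
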