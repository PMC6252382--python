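name	LD-whole
model_order	12
channel	Fp1
channel	Fp2
channel	F7
channel	F3
channel	Fz
channel	F4
channel	F8
channel	T7
channel	C3
channel	C4
channel	T8
channel	P7
channel	P3
channel	Pz
channel	P4
channel	P8
channel	O1
channel	O2
channel	Oz
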