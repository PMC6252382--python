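name	HD-SM
model_order	9
channel	T7
channel	C3
channel	C4
channel	T8
channel	E20
channel	E21
channel	E22
channel	E23
channel	E24
channel	E27
channel	E28
channel	E32
channel	E36
channel	E40
channel	E53
channel	E57
channel	E70
channel	E74
channel	E87
channel	E91
channel	E108
channel	E125
channel	E129
channel	E142
channel	E146
channel	E163
channel	E180
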