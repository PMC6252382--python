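name	HD-whole
model_order	1
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
channel	E20
channel	E21
channel	E22
channel	E23
channel	E24
channel	E25
channel	E26
channel	E27
channel	E28
channel	E29
channel	E30
channel	E31
channel	E32
channel	E33
channel	E34
channel	E35
channel	E36
channel	E37
channel	E38
channel	E39
channel	E40
channel	E41
channel	E42
channel	E43
channel	E44
channel	E45
channel	E46
channel	E47
channel	E48
channel	E49
channel	E50
channel	E51
channel	E52
channel	E53
channel	E54
channel	E55
channel	E56
channel	E57
channel	E58
channel	E59
channel	E60
channel	E61
channel	E62
channel	E63
channel	E64
channel	E65
channel	E66
channel	E67
channel	E68
channel	E69
channel	E70
channel	E71
channel	E72
channel	E73
channel	E74
channel	E75
channel	E76
channel	E77
channel	E78
channel	E79
channel	E80
channel	E81
channel	E82
channel	E83
channel	E84
channel	E85
channel	E86
channel	E87
channel	E88
channel	E89
channel	E90
channel	E91
channel	E92
channel	E93
channel	E94
channel	E95
channel	E96
channel	E97
channel	E98
channel	E99
channel	E100
channel	E101
channel	E102
channel	E103
channel	E104
channel	E105
channel	E106
channel	E107
channel	E108
channel	E109
channel	E110
channel	E111
channel	E112
channel	E113
channel	E114
channel	E115
channel	E116
channel	E117
channel	E118
channel	E119
channel	E120
channel	E121
channel	E122
channel	E123
channel	E124
channel	E125
channel	E126
channel	E127
channel	E128
channel	E129
channel	E130
channel	E131
channel	E132
channel	E133
channel	E134
channel	E135
channel	E136
channel	E137
channel	E138
channel	E139
channel	E140
channel	E141
channel	E142
channel	E143
channel	E144
channel	E145
channel	E146
channel	E147
channel	E148
channel	E149
channel	E150
channel	E151
channel	E152
channel	E153
channel	E154
channel	E155
channel	E156
channel	E157
channel	E158
channel	E159
channel	E160
channel	E161
channel	E162
channel	E163
channel	E164
channel	E165
channel	E166
channel	E167
channel	E168
channel	E169
channel	E170
channel	E171
channel	E172
channel	E173
channel	E174
channel	E175
channel	E176
channel	E177
channel	E178
channel	E179
channel	E180
channel	E181
channel	E182
channel	E183
channel	E184
channel	E185
channel	E186
channel	E187
channel	E188
channel	E189
channel	E190
channel	E191
channel	E192
channel	E193
channel	E194
channel	E195
channel	E196
channel	E197
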