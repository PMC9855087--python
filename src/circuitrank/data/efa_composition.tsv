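name	shorthand	classes	g_per_100g
Palmitic	C16:0	SFA	0.47
Palmitoleic	C16:1 n7	MUFA	0.28
Hexadecaenoic	C16:4 n1	PUFA	0.09
Stearic	C18:0	SFA	0.78
Oleic	C18:1 n9	omega9;MUFA	1.24
Vaccenic	C18:1 n7	MUFA	0.51
Linoleic	C18:2 n6	omega6;PUFA	0.19
Linolenic	C18:3 n3	omega3;PUFA	0.11
Stearidonic	C18:4 n3	omega3;PUFA	0.43
Arachidic	C20:0	SFA	1.44
Eicosenoic	C20:1 n9	omega9;MUFA	2.78
Gondonic	C20:1 n7	MUFA	0.38
Arachidonic	C20:4 n6	omega6;PUFA	1.05
Eicosatetraenoic	C20:4 n3	omega3	1.15
Eicosapentaenoic	C20:5 n3	omega3;PUFA	18.36
Behenic	C22:0	SFA	1.44
Erucic	C22:1 n11	MUFA	2.78
Adrenic	C22:4 n6	PUFA	0.46
Docosapentaenoic	C22:5 n6	omega6;PUFA	0.90
Docosapentaenoic	C22:5 n3	omega3;PUFA	6.81
Lignoceric	C24:0	SFA	0.44
Docosahexaenoic	C22:6 n3	omega3;PUFA	40.73
Nervonic	C24:1 n9	omega9;MUFA	2.17
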