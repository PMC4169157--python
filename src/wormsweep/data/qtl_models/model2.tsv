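chromosome	window	favored_background
I	12	CB4856
I	38	CB4856
I	63	CB4856
II	12	N2
II	38	N2
II	64	MY2
III	11	JU258
III	34	JU258
III	57	JU258
IV	11	AB1
IV	33	AB1
IV	55	AB1
IV	77	AB1
V	10	CB4856
V	31	CB4856
V	52	CB4856
V	73	N2
V	94	N2
X	11	MY2
X	33	MY2
X	55	MY2
X	77	MY2
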