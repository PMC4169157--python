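chromosome	window	favored_background
I	19	CB4856
I	57	CB4856
II	12	N2
II	38	N2
II	64	MY2
III	17	JU258
III	51	JU258
IV	14	AB1
IV	44	AB1
IV	73	AB1
V	17	CB4856
V	52	CB4856
V	87	N2
X	14	MY2
X	44	MY2
X	74	MY2
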