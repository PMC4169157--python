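chromosome	window	favored_background
I	19	CB4856
I	57	CB4856
II	19	N2
II	57	MY2
III	34	JU258
IV	22	AB1
IV	66	AB1
V	26	CB4856
V	78	N2
X	22	MY2
X	66	MY2
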