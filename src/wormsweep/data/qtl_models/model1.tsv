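chromosome	window	favored_background
I	2	CB4856
I	8	CB4856
I	14	CB4856
I	20	CB4856
I	26	CB4856
I	32	CB4856
I	38	CB4856
I	43	CB4856
I	49	CB4856
I	55	CB4856
I	61	CB4856
I	67	CB4856
I	73	CB4856
II	2	N2
II	8	N2
II	14	N2
II	20	N2
II	26	N2
II	32	N2
II	38	N2
II	44	MY2
II	50	MY2
II	56	MY2
II	62	MY2
II	68	MY2
II	74	MY2
III	3	JU258
III	9	JU258
III	15	JU258
III	21	JU258
III	28	JU258
III	34	JU258
III	40	JU258
III	47	JU258
III	53	JU258
III	59	JU258
III	65	JU258
IV	3	AB1
IV	9	AB1
IV	15	AB1
IV	22	AB1
IV	28	AB1
IV	34	AB1
IV	40	AB1
IV	47	AB1
IV	53	AB1
IV	59	AB1
IV	66	AB1
IV	72	AB1
IV	78	AB1
IV	84	AB1
V	3	CB4856
V	9	CB4856
V	15	CB4856
V	21	CB4856
V	27	CB4856
V	33	CB4856
V	40	CB4856
V	46	CB4856
V	52	CB4856
V	58	N2
V	64	N2
V	71	N2
V	77	N2
V	83	N2
V	89	N2
V	95	N2
V	101	N2
X	2	MY2
X	8	MY2
X	14	MY2
X	20	MY2
X	26	MY2
X	32	MY2
X	38	MY2
X	44	MY2
X	50	MY2
X	56	MY2
X	62	MY2
X	68	MY2
X	74	MY2
X	80	MY2
X	86	MY2
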