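Site	Group	Reads	Classified reads	Classified percent	Genera observed	Coverage percent	Pielou evenness	Chao1	Chao1 se
Eiland	spring	720	698	97	49	62	0.57	79	19
Mphephu	spring	721	673	93	92	68	0.69	135	20
Sagole	spring	794	662	83	113	59	0.72	190	30
Siloam	spring	568	515	91	119	57	0.78	209	34
Souting	spring	132	120	91	39	57	0.83	68	21
Tshipise	spring	120	110	92	30	47	0.74	64	31
Be326_2011	subsurface	14227	13328	94	551	77	0.80	716	37
Be326_2012	subsurface	23343	21806	93	634	86	0.80	739	25
Dr5IPC	subsurface	18215	15876	87	549	84	0.80	653	24
FI88	subsurface	18719	17282	92	573	79	0.78	725	34
MM51940	subsurface	22984	20768	90	655	86	0.80	760	24
NO14	subsurface	22237	20676	93	640	86	0.79	744	24
TT109	subsurface	19367	17792	92	569	83	0.77	689	27
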