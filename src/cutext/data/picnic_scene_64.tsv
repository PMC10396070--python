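entry_id	canonical_label	category	ambiguity	variants
1	man	entity	unambiguous	man|noun;husband|noun;father|noun;dad|noun
2	woman	entity	unambiguous	woman|noun;wife|noun;mother|noun;mom|noun;lady|noun
3	boy	entity	unambiguous	boy|noun;son|noun
4	dog	entity	unambiguous	dog|noun;puppy|noun
5	kite	entity	unambiguous	kite|noun
6	sailboat	entity	unambiguous	sailboat|noun;boat|noun
7	lake	entity	unambiguous	lake|noun;pond|noun
8	tree	entity	unambiguous	tree|noun
9	house	entity	unambiguous	house|noun;home|noun
10	flag	entity	unambiguous	flag|noun
11	blanket	entity	unambiguous	blanket|noun
12	girl/daughter	entity	unambiguous	girl|noun;daughter|noun
13	basket	entity	unambiguous	basket|noun;hamper|noun
14	picnic	entity	unambiguous	picnic|noun
15	book	entity	unambiguous	book|noun
16	radio	entity	unambiguous	radio|noun
17	pail	entity	unambiguous	pail|noun;bucket|noun
18	shovel	entity	unambiguous	shovel|noun;spade|noun
19	sand	entity	unambiguous	sand|noun
20	pier	entity	unambiguous	pier|noun;dock|noun;wharf|noun
21	fisherman	entity	unambiguous	fisherman|noun
22	fishing pole	entity	unambiguous	pole|noun;rod|noun
23	drink	entity	unambiguous	drink|noun;beverage|noun;lemonade|noun
24	cup	entity	unambiguous	cup|noun;glass|noun
25	shoe	entity	unambiguous	shoe|noun;sneaker|noun
26	couple	entity	unambiguous	couple|noun
27	family	entity	unambiguous	family|noun
28	people	entity	ambiguous	people|noun;person|noun
29	child	entity	ambiguous	child|noun;kid|noun
30	water	entity	ambiguous	water|noun
31	garage	entity	unambiguous	garage|noun
32	door	entity	ambiguous	door|noun
33	window	entity	ambiguous	window|noun
34	branch	entity	ambiguous	branch|noun
35	shore	entity	unambiguous	shore|noun;beach|noun;bank|noun
36	grass	entity	unambiguous	grass|noun;lawn|noun
37	sky	entity	unambiguous	sky|noun
38	music	entity	unambiguous	music|noun;song|noun
39	string	entity	unambiguous	string|noun
40	wind	entity	unambiguous	wind|noun;breeze|noun
41	fly	action	unambiguous	fly|verb
42	run	action	ambiguous	run|verb;race|verb
43	pour	action	unambiguous	pour|verb
44	read	action	unambiguous	read|verb
45	fish	action	unambiguous	fish|verb
46	sail	action	unambiguous	sail|verb;float|verb
47	play	action	ambiguous	play|verb
48	sit	action	ambiguous	sit|verb
49	dig	action	unambiguous	dig|verb
50	listen	action	unambiguous	listen|verb
51	wave	action	ambiguous	wave|verb
52	hold	action	ambiguous	hold|verb
53	wear	action	ambiguous	wear|verb
54	relax	action	ambiguous	relax|verb;rest|verb
55	stand	action	ambiguous	stand|verb
56	build	action	unambiguous	build|verb
57	smile	action	ambiguous	smile|verb
58	eat	action	ambiguous	eat|verb
59	red	property	ambiguous	red|adjective
60	barefoot	property	unambiguous	barefoot|adjective
61	sunny	property	unambiguous	sunny|adjective;sunshine|noun
62	windy	property	unambiguous	windy|adjective;breezy|adjective
63	little	property	ambiguous	little|adjective;small|adjective;young|adjective
64	happy	property	ambiguous	happy|adjective;cheerful|adjective
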