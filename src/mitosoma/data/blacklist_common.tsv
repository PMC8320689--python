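pos	ref	alt	source
73	A	G	common-germline
146	T	C	common-germline
152	T	C	common-germline
195	T	C	common-germline
263	A	G	common-germline
489	T	C	common-germline
750	A	G	common-germline
1438	A	G	common-germline
2706	A	G	common-germline
3197	T	C	common-germline
4769	A	G	common-germline
7028	C	T	common-germline
8860	A	G	common-germline
9055	G	A	common-germline
10398	A	G	common-germline
10400	C	T	common-germline
11251	A	G	common-germline
11719	G	A	common-germline
12705	C	T	common-germline
13368	G	A	common-germline
14766	C	T	common-germline
15326	A	G	common-germline
16189	T	C	common-germline
16223	C	T	common-germline
16519	T	C	common-germline
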