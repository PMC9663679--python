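# Cumulative rule-out counts for the Glasgow-Blatchford score (cutoff = "score <= k"),
# stratified by presence of a high-risk endoscopic lesion (HREL). Totals: 35 with, 80 without.
cutoff	cum_with_hrel	cum_without_hrel
0	0	3
1	1	4
2	2	6
3	3	12
4	3	13
5	3	13
6	3	19
7	4	26
8	4	28
9	6	33
10	10	42
11	17	52
12	23	62
13	26	69
14	27	72
15	32	75
16	34	79
17	35	80
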