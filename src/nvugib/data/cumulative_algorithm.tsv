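# Cumulative rule-out counts for the combined GBS + nasogastric-aspirate score
# (bloody aspirate -> score 23; otherwise score = GBS), cutoff = "score <= k",
# stratified by HREL status. Totals: 35 with, 80 without (bloody patients, all
# scoring 23, enter the cumulative counts only at cutoff 23).
cutoff	cum_with_hrel	cum_without_hrel
0	0	3
1	0	4
2	0	6
3	0	11
4	0	12
5	0	12
6	0	16
7	0	21
8	0	23
9	0	27
10	1	36
11	2	44
12	3	53
13	6	59
14	7	62
15	10	64
16	11	68
17	11	69
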