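age_lo	age_hi	population
0	5	18986520
5	10	19919840
10	15	20056779
15	20	19819518
20	25	18257225
25	30	17722067
30	35	19511370
35	40	22179956
40	45	22479229
45	50	19805793
50	55	17224359
55	60	13307234
60	65	10654272
65	70	9409940
70	75	8725574
75	80	7414559
80	85	4900234
85		4259173
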