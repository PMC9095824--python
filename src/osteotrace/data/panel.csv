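position,pool
489,1
653,1
795,1
1075,1
1402,1
1569,1
1767,1
2206,1
2291,1
2572,1
2751,1
2792,1
3130,1
3216,1
3602,1
3645,1
3666,1
3711,1
3831,1
3960,1
4014,1
4035,1
4255,1
4265,2
4477,2
4515,2
4556,2
4875,2
5214,2
5652,2
5743,2
5982,2
6024,2
6038,2
6161,2
6315,2
6408,2
6467,2
6889,2
6949,2
7062,2
7372,2
7453,2
7463,2
7508,2
7515,2
7610,2
7660,2
7680,2
7918,2
8021,2
8216,2
8228,2
8325,2
8327,2
8440,2
8546,2
8701,2
8726,2
8732,3
8734,3
9171,3
9326,3
9381,3
9540,3
9586,3
9900,3
10102,3
10186,3
10398,3
10400,3
10508,3
10596,3
10798,3
10807,3
10873,3
10884,3
11099,3
11268,3
11442,3
11467,3
11676,3
11837,3
11882,3
12009,3
12308,3
12372,3
12589,3
12596,3
12705,3
12851,4
12875,4
12987,4
13189,4
13238,4
13512,4
13591,4
13813,4
13981,4
14043,4
14090,4
14579,4
14705,4
14771,4
14783,4
15043,4
15047,4
15222,4
15513,4
15772,4
15806,4
16148,4
16180,4
16223,4
16405,4
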