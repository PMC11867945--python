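# Synthetic life table for the 50-75 screening target population.
# Gompertz hazard qx = a*exp(b*age), b=0.09, a calibrated so the
# uniform age-weighted mortality over ages 50-75 equals 0.0063.
# This is a synthetic stand-in, not census data.
age,qx
50,0.001644
51,0.001799
52,0.001969
53,0.002154
54,0.002357
55,0.002579
56,0.002822
57,0.003087
58,0.003378
59,0.003696
60,0.004044
61,0.004425
62,0.004842
63,0.005298
64,0.005797
65,0.006343
66,0.00694
67,0.007594
68,0.008309
69,0.009091
70,0.009948
71,0.010884
72,0.011909
73,0.013031
74,0.014258
75,0.015601
76,0.01707
77,0.018678
78,0.020437
79,0.022361
80,0.024467
81,0.026771
82,0.029292
83,0.032051
84,0.035069
85,0.038372
86,0.041986
87,0.04594
88,0.050266
89,0.055
90,0.060179
91,0.065847
92,0.072048
93,0.078833
94,0.086257
95,0.09438
96,0.103268
97,0.112993
98,0.123634
99,0.135277
100,0.148017
101,0.161956
102,0.177208
103,0.193897
104,0.212157
105,0.232137
106,0.253998
107,0.277918
108,0.304091
109,0.332728
110,0.364063
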