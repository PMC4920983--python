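Pat. No,MRI-1 no margin,FET-1 no margin,MRI-1 +5 mm margin,FET-1 +5 mm margin,MRI-1 +7 mm margin,FET-1 +7 mm margin,MRI-1 +10 mm margin,FET-1 +10 mm margin
1,0.27,0.33,0.80,0.95,0.87,1.00,0.93,1.00
2,0.08,0.098,0.49,0.61,0.52,0.76,0.70,1.00
3,0.21,0.34,0.61,0.95,0.67,1.00,0.83,1.00
4,0.33,0.42,0.74,0.94,0.85,1.00,0.86,1.00
5,0.25,0.35,0.92,0.96,0.99,1.00,1.00,1.00
6,0.05,0.39,0.19,0.85,0.23,0.92,0.33,0.97
7,0.00,0.25,0.00,0.831,0.00,0.91,0.00,0.98
8,0.20,0.32,0.76,0.93,1.00,1.00,1.00,1.00
9,0.08,0.11,0.79,0.84,0.88,0.91,0.90,0.95
10,0.16,0.05,0.55,0.42,0.62,0.54,0.84,0.82
11,0.42,0.63,0.51,0.96,0.578,0.97,0.77,1.00
12,0.30,0.44,0.79,1.00,0.90,1.00,0.96,1.00
13,0.22,0.34,0.91,1.00,1.00,1.00,1.00,1.00
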