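Pat. No,PTV-2 MRI standard (ml),PTV FET-1 +5 mm margin (ml),PTV FET-1 +7 mm margin (ml),PTV FET-1 +10 mm margin (ml)
1,245,122,147,214
2,164,98,118,163
3,117,92,112,143
4,248,125,150,194
5,161,101,114,146
6,256,182,213,286
7,224,106,126,166
8,348,216,253,308
9,209,161,187,259
10,160,138,160,216
11,364,233,263,304
12,386,265,297,342
13,231,175,197,258
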