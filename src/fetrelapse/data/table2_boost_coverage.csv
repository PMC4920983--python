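Pat. No,FET-2 (ml),Part of FET-2 in PTV-1 (ml),Fraction of FET-2 in PTV-1 (%),Fraction of FET-2 in PTV-2 (%)
1,3.7,1.2,11.5,100
2,10.9,1.1,15.9,100
3,11.3,3.8,55.9,100
4,12.2,5.1,38.9,100
5,13.9,4.9,36.6,100
6,35.1,13.7,91.3,100
7,6.2,1.6,23.9,100
8,22.1,9.5,37.7,100
9,5.6,0.6,12.8,100
10,56.0,2.8,41.2,100
11,46.7,29.4,46.7,100
12,66.8,29.0,49.2,100
13,12.8,4.4,48.4,100
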