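Pat. No,FET-1 (ml),MRI-1 (ml),Intersect FET-1 ∩ MRI-1 (ml),Intersect FET-1 ∩ MRI-1 (% of FET-1),FET-2 (ml),MRI-2 (ml),Intersect FET-2 ∩ MRI-2 (ml),Intersect FET-2 ∩ MRI-2 (% of FET-2)
1,10.4,0.8,0.4,3.8,3.7,3.7,0.0,0.0
2,6.9,0.6,0.2,2.9,10.9,8.9,0.7,8.7
3,6.8,3.7,2.2,32.4,11.3,8.1,5.0,44.2
4,1.1,6.8,1.3,9.9,12.2,9.3,7.6,62.3
5,13.4,6.0,3.5,26.1,13.9,12.0,1.1,7.9
6,15.0,1.3,0.5,3.3,35.1,16.2,23.5,67.0
7,6.7,6.4,0.0,0.0,6.2,19.4,0.8,12.9
8,25.2,1.3,1.3,5.2,22.1,26.8,10.0,45.3
9,4.7,6.5,1.5,31.9,5.6,27.0,5.6,100.0
10,6.8,4.9,1.6,23.5,56.0,39.6,0.0,0.0
11,62.9,19.4,12.0,19.1,46.7,41.8,23.4,50.1
12,59.0,19.5,11.3,19.2,66.8,43.5,5.5,8.2
13,9.1,1.1,1.1,12.1,12.8,113.0,1.7,13.3
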