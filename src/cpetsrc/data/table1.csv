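Sample,MBPB (mmHg),MBPA (mmHg),r_i (%),z_i,Label
1,242,202,16.529,2.209,Strong
2,229,195,14.847,1.792,Strong
3,221,192,13.122,1.365,Strong
4,241,212,12.033,1.094,Strong
5,235,213,9.362,0.432,Strong
6,253,230,9.091,0.365,Strong
7,223,203,8.969,0.334,Strong
8,249,227,8.835,0.301,Strong
9,209,191,8.612,0.246,Strong
10,244,223,8.607,0.245,Strong
11,214,196,8.411,0.196,Strong
12,246,226,8.130,0.127,Strong
13,204,188,7.843,0.055,Strong
14,244,225,7.787,0.041,Strong
15,244,226,7.377,-0.060,Weak
16,231,214,7.359,-0.065,Weak
17,240,223,7.083,-0.133,Weak
18,231,215,6.926,-0.172,Weak
19,214,207,3.271,-1.079,Weak
20,221,214,3.167,-1.104,Weak
21,222,216,2.703,-1.220,Weak
22,211,208,1.422,-1.537,Weak
23,207,205,0.966,-1.650,Weak
24,207,208,0.483,-1.770,Weak
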