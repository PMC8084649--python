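Sample,PEBP (mmHg),R6BP (mmHg),dBP (mmHg),Predicted label,Real label
1,242,267,-25,Weak,Strong
2,233,260,-27,Weak,Strong
3,199,170,29,Strong,Strong
4,236,216,20,Strong,Strong
5,190,223,-33,Weak,Strong
6,238,246,-8,Weak,Strong
7,209,205,4,Strong,Strong
8,274,256,18,Strong,Strong
9,201,203,-2,Weak,Strong
10,224,214,10,Strong,Strong
11,204,211,-7,Weak,Strong
12,262,255,7,Strong,Strong
13,216,218,-2,Weak,Strong
14,219,194,25,Strong,Strong
15,222,232,-10,Weak,Weak
16,245,229,16,Strong,Weak
17,247,250,-3,Weak,Weak
18,176,173,3,Strong,Weak
19,233,225,8,Strong,Weak
20,219,227,-8,Weak,Weak
21,205,206,-1,Weak,Weak
22,223,235,-12,Weak,Weak
23,216,242,-26,Weak,Weak
24,224,185,39,Strong,Weak
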