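age_lo,age_hi,n,y,predicted
0,1,9934747,1,0
1,5,38690768,2,0
5,10,48506058,2,6
10,15,49881935,35,44
15,20,50447512,104,164
20,25,51612785,337,370
25,30,54071811,847,965
30,35,54194486,1829,2080
35,40,50363957,3420,3534
40,45,46029771,6174,6698
45,50,40674188,10950,11072
50,55,36070434,18716,18256
55,60,31084543,27438,25875
60,65,26507762,37155,34867
65,70,22772688,47202,45156
70,75,18785224,53190,52810
75,80,14592602,52887,53479
80,85,9751212,42589,41517
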