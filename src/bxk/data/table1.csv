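subject_id,age,service_years,d1_post,d2_pre,d2_post,d3_pre,d3_post
1,33,11,0.9,20.2,1.3,13.4,7.0
3,34,10,-1.7,12.3,-4.2,0.2,-0.4
4,46,19,-11.7,11.8,-5.0,1.7,-6.6
6,50,22,2.0,20.0,1.9,9.7,8.3
7,47,26,-5.2,2.5,7.4,6.7,-3.5
8,43,18,0.2,9.5,1.7,8.0,3.1
9,35,8,-3.2,5.8,-4.2,8.6,-1.0
11,43,9,-6.3,15.6,-0.8,11.9,0.5
12,37,12,-7.2,-2.3,2.5,7.1,-3.4
14,52,10,-6.2,17.3,-0.4,10.3,7.9
16,46,19,-16.2,14.4,-6.0,-11.8,-1.2
17,45,15,-7.7,-4.3,-0.5,-0.2,-4.0
18,36,8,-6.8,17.1,-5.6,0.0,-1.8
19,42,12,3.1,17.3,4.3,13.8,8.6
20,46,19,-12.1,3.1,-7.4,-6.3,-2.9
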