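subject,doctor_score,imu_score
1,0,0.2732
2,4,0.7906
3,5,0.7266
4,3,0.3859
5,3,0.3620
6,5,0.5506
7,10,1.1644
8,6,1.1418
9,3,0.5846
10,3,0.4490
11,9,4.0168
12,9,2.3792
13,3,0.7701
14,0,0.3567
15,0,0.1239
16,0,0.2664
17,4,0.4509
18,0,0.1600
19,3,0.3820
20,0,0.2640
21,5,0.7700
22,0,0.2070
23,7,0.8810
24,3,0.4000
25,0,0.1640
26,0,0.1860
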