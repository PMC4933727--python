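condition,row,col,azimuth_deg,likelihood
A,0,0,-22.5,1.0
A,0,1,-7.5,0.9957
A,0,2,7.5,0.059
A,0,3,22.5,0.102
A,1,0,-22.5,0.9902
A,1,1,-7.5,0.9466
A,1,2,7.5,-0.0565
A,1,3,22.5,0.0299
B,0,0,7.5,0.059
B,0,1,22.5,0.2098
B,0,2,37.5,0.0703
B,0,3,52.5,0.0577
B,1,0,7.5,-0.0565
B,1,1,22.5,0.0299
B,1,2,37.5,0.0004
B,1,3,52.5,0.1196
C,0,0,7.5,0.6392
C,0,1,22.5,0.895
C,0,2,37.5,0.0747
C,0,3,52.5,0.103
C,1,0,7.5,0.8778
C,1,1,22.5,0.9742
C,1,2,37.5,0.0131
C,1,3,52.5,0.0944
D,0,0,-22.5,0.9694
D,0,1,-7.5,0.9122
D,0,2,7.5,0.6392
D,0,3,22.5,0.895
D,1,0,-22.5,0.9745
D,1,1,-7.5,0.8489
D,1,2,7.5,0.8778
D,1,3,22.5,0.9742
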