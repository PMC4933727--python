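condition,row,col,azimuth_deg,likelihood
A,0,0,-22.5,0.102
A,0,1,-7.5,0.0187
A,0,2,7.5,0.6706
A,0,3,22.5,0.3912
A,1,0,-22.5,0.0709
A,1,1,-7.5,-0.0051
A,1,2,7.5,0.5286
A,1,3,22.5,0.5025
B,0,0,7.5,0.6706
B,0,1,22.5,0.3912
B,0,2,37.5,0.712
B,0,3,52.5,0.5777
B,1,0,7.5,0.5286
B,1,1,22.5,0.5025
B,1,2,37.5,0.7534
B,1,3,52.5,0.7057
C,0,0,7.5,0.2539
C,0,1,22.5,-0.0022
C,0,2,37.5,0.6639
C,0,3,52.5,0.6693
C,1,0,7.5,0.1145
C,1,1,22.5,0.2336
C,1,2,37.5,0.5569
C,1,3,52.5,0.5951
D,0,0,-22.5,0.0351
D,0,1,-7.5,0.0351
D,0,2,7.5,0.2539
D,0,3,22.5,-0.0022
D,1,0,-22.5,0.1745
D,1,1,-7.5,-0.0227
D,1,2,7.5,0.1145
D,1,3,22.5,0.2336
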