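condition,row,col,azimuth_deg,likelihood
A,0,0,-22.5,1.0
A,0,1,-7.5,1.0
A,0,2,7.5,0.5183
A,0,3,22.5,0.6708
A,1,0,-22.5,0.9984
A,1,1,-7.5,1.0
A,1,2,7.5,0.6481
A,1,3,22.5,0.6655
B,0,0,7.5,0.5183
B,0,1,22.5,0.6708
B,0,2,37.5,0.5263
B,0,3,52.5,0.473
B,1,0,7.5,0.6481
B,1,1,22.5,0.6655
B,1,2,37.5,0.3323
B,1,3,52.5,0.4261
C,0,0,7.5,0.8348
C,0,1,22.5,0.9665
C,0,2,37.5,0.5182
C,0,3,52.5,0.4522
C,1,0,7.5,0.9557
C,1,1,22.5,0.7925
C,1,2,37.5,0.4062
C,1,3,52.5,0.5116
D,0,0,-22.5,0.8812
D,0,1,-7.5,0.9831
D,0,2,7.5,0.8348
D,0,3,22.5,0.9665
D,1,0,-22.5,1.0
D,1,1,-7.5,0.9867
D,1,2,7.5,0.9557
D,1,3,22.5,0.7925
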