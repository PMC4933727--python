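condition,row,col,azimuth_deg,likelihood
A,0,0,-22.5,-0.11
A,0,1,-7.5,0.0437
A,0,2,7.5,0.9752
A,0,3,22.5,0.9816
A,1,0,-22.5,0.0954
A,1,1,-7.5,-0.1327
A,1,2,7.5,0.9513
A,1,3,22.5,0.9413
B,0,0,7.5,0.9752
B,0,1,22.5,0.9816
B,0,2,37.5,0.9297
B,0,3,52.5,0.9423
B,1,0,7.5,0.9513
B,1,1,22.5,0.9413
B,1,2,37.5,0.9996
B,1,3,52.5,0.8804
C,0,0,7.5,0.1222
C,0,1,22.5,0.105
C,0,2,37.5,0.9253
C,0,3,52.5,0.7507
C,1,0,7.5,0.1562
C,1,1,22.5,0.0258
C,1,2,37.5,0.899
C,1,3,52.5,0.9656
D,0,0,-22.5,-0.1675
D,0,1,-7.5,0.0878
D,0,2,7.5,0.1222
D,0,3,22.5,0.105
D,1,0,-22.5,-0.0647
D,1,1,-7.5,-0.1278
D,1,2,7.5,0.1562
D,1,3,22.5,0.0258
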