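particle,Z,A,energy_mev_u,let_kev_um
H,1,1,1.0,26.0
H,1,1,1.283569,21.560507
H,1,1,1.647549,17.879057
H,1,1,2.114743,14.826213
H,1,1,2.714418,12.294641
H,1,1,3.484142,10.195334
H,1,1,4.472136,8.454484
H,1,1,5.740294,7.010883
H,1,1,7.368063,5.813777
H,1,1,9.457416,4.821076
H,1,1,12.139245,3.997879
H,1,1,15.581556,3.315242
H,1,1,20.0,2.749165
H,1,1,25.671377,2.279746
H,1,1,32.950979,1.89048
H,1,1,42.294851,1.567681
H,1,1,54.288352,1.3
H,1,1,69.682838,1.078025
H,1,1,89.442719,0.893953
H,1,1,114.805887,0.741311
H,1,1,147.36126,0.614732
H,1,1,189.148322,0.509767
H,1,1,242.784892,0.422724
H,1,1,311.631123,0.350544
H,1,1,400.0,0.290689
He,2,4,1.0,99.249847
He,2,4,1.283569,83.727273
He,2,4,1.647549,70.275374
He,2,4,2.114743,58.738756
He,2,4,2.714418,48.941853
He,2,4,3.484142,40.691484
He,2,4,4.472136,33.787302
He,2,4,5.740294,28.034264
He,2,4,7.368063,23.252652
He,2,4,9.457416,19.283743
He,2,4,12.139245,15.991405
He,2,4,15.581556,13.26095
He,2,4,20.0,10.996659
He,2,4,25.671377,9.118984
He,2,4,32.950979,7.56192
He,2,4,42.294851,6.270724
He,2,4,54.288352,5.2
He,2,4,69.682838,4.312101
He,2,4,89.442719,3.575811
He,2,4,114.805887,2.965243
He,2,4,147.36126,2.458928
He,2,4,189.148322,2.039067
He,2,4,242.784892,1.690897
He,2,4,311.631123,1.402177
He,2,4,400.0,1.162755
Li,3,7,1.0,207.197819
Li,3,7,1.283569,178.300966
Li,3,7,1.647549,152.15419
Li,3,7,2.114743,128.849688
Li,3,7,2.714418,108.404606
Li,3,7,3.484142,90.734998
Li,3,7,4.472136,75.661054
Li,3,7,5.740294,62.933374
Li,3,7,7.368063,52.266944
Li,3,7,9.457416,43.372008
Li,3,7,12.139245,35.976073
Li,3,7,15.581556,29.836026
Li,3,7,20.0,24.742252
Li,3,7,25.671377,20.517674
Li,3,7,32.950979,17.014315
Li,3,7,42.294851,14.109129
Li,3,7,54.288352,11.7
Li,3,7,69.682838,9.702228
Li,3,7,89.442719,8.045575
Li,3,7,114.805887,6.671796
Li,3,7,147.36126,5.532588
Li,3,7,189.148322,4.5879
Li,3,7,242.784892,3.804518
Li,3,7,311.631123,3.154897
Li,3,7,400.0,2.6162
Be,4,9,1.0,338.594308
Be,4,9,1.283569,296.540974
Be,4,9,1.647549,257.110311
Be,4,9,2.114743,220.753787
Be,4,9,2.714418,187.854484
Be,4,9,3.484142,158.640443
Be,4,9,4.472136,133.149755
Be,4,9,5.740294,111.24266
Be,4,9,7.368063,92.644262
Be,4,9,9.457416,76.998768
Be,4,9,12.139245,63.920098
Be,4,9,15.581556,53.030263
Be,4,9,20.0,43.983093
Be,4,9,25.671377,36.47513
Be,4,9,32.950979,30.247523
Be,4,9,42.294851,25.082872
Be,4,9,54.288352,20.799996
Be,4,9,69.682838,17.248405
Be,4,9,89.442719,14.303245
Be,4,9,114.805887,11.86097
Be,4,9,147.36126,9.835713
Be,4,9,189.148322,8.156268
Be,4,9,242.784892,6.763587
Be,4,9,311.631123,5.608706
Be,4,9,400.0,4.651021
B,5,11,1.0,485.762375
B,5,11,1.283569,431.778684
B,5,11,1.647549,379.65508
B,5,11,2.114743,330.188397
B,5,11,2.714418,284.181551
B,5,11,3.484142,242.28668
B,5,11,4.472136,204.908282
B,5,11,5.740294,172.17396
B,5,11,7.368063,143.96095
B,5,11,9.457416,119.956815
B,5,11,12.139245,99.732099
B,5,11,15.581556,82.807681
B,5,11,20.0,68.706665
B,5,11,25.671377,56.987544
B,5,11,32.950979,47.260543
B,5,11,42.294851,39.191724
B,5,11,54.288352,32.499945
B,5,11,69.682838,26.950626
B,5,11,89.442719,22.34882
B,5,11,114.805887,18.532766
B,5,11,147.36126,15.368301
B,5,11,189.148322,12.744168
B,5,11,242.784892,10.568105
B,5,11,311.631123,8.763604
B,5,11,400.0,7.267221
C,6,12,1.0,643.636696
C,6,12,1.283569,579.267779
C,6,12,1.647549,515.560718
C,6,12,2.114743,453.585754
C,6,12,2.714418,394.544045
C,6,12,3.484142,339.546011
C,6,12,4.472136,289.445969
C,6,12,5.740294,244.755102
C,6,12,7.368063,205.630328
C,6,12,9.457416,171.920791
C,6,12,12.139245,143.247564
C,6,12,15.581556,119.093097
C,6,12,20.0,98.882202
C,6,12,25.671377,82.043756
C,6,12,32.950979,68.049817
C,6,12,42.294851,56.434701
C,6,12,54.288352,46.79961
C,6,12,69.682838,38.80884
C,6,12,89.442719,32.18229
C,6,12,114.805887,26.687181
C,6,12,147.36126,22.130353
C,6,12,189.148322,18.351602
C,6,12,242.784892,15.218071
C,6,12,311.631123,12.61959
C,6,12,400.0,10.464798
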