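particle,Z,A,energy_mev_u,let_kev_um,cl_per_um
H,1,1,1.0,26.0,0.01650498
H,1,1,1.283569,21.560507,0.01219652
H,1,1,1.647549,17.879057,0.00912634
H,1,1,2.114743,14.826213,0.00690643
H,1,1,2.714418,12.294641,0.00527964
H,1,1,3.484142,10.195334,0.00407281
H,1,1,4.472136,8.454484,0.00316746
H,1,1,5.740294,7.010883,0.00248135
H,1,1,7.368063,5.813777,0.00195658
H,1,1,9.457416,4.821076,0.00155183
H,1,1,12.139245,3.997879,0.00123726
H,1,1,15.581556,3.315242,0.00099108
H,1,1,20.0,2.749165,0.0007972
H,1,1,25.671377,2.279746,0.00064364
H,1,1,32.950979,1.89048,0.00052137
H,1,1,42.294851,1.567681,0.00042358
H,1,1,54.288352,1.3,0.00034502
H,1,1,69.682838,1.078025,0.00028167
H,1,1,89.442719,0.893953,0.00023042
H,1,1,114.805887,0.741311,0.00018883
H,1,1,147.36126,0.614732,0.00015499
H,1,1,189.148322,0.509767,0.00012738
H,1,1,242.784892,0.422724,0.00010482
H,1,1,311.631123,0.350544,8.634e-05
H,1,1,400.0,0.290689,7.118e-05
He,2,4,1.0,99.249847,0.23012934
He,2,4,1.283569,83.727273,0.1564628
He,2,4,1.647549,70.275374,0.10686086
He,2,4,2.114743,58.738756,0.07356212
He,2,4,2.714418,48.941853,0.05119194
He,2,4,3.484142,40.691484,0.03608937
He,2,4,4.472136,33.787302,0.02580275
He,2,4,5.740294,28.034264,0.01871271
He,2,4,7.368063,23.252652,0.01375834
He,2,4,9.457416,19.283743,0.0102459
He,2,4,12.139245,15.991405,0.00771981
He,2,4,15.581556,13.26095,0.00587818
He,2,4,20.0,10.996659,0.00451849
He,2,4,25.671377,9.118984,0.00350293
He,2,4,32.950979,7.56192,0.00273636
He,2,4,42.294851,6.270724,0.00215217
He,2,4,54.288352,5.2,0.00170306
He,2,4,69.682838,4.312101,0.00135506
He,2,4,89.442719,3.575811,0.00108346
He,2,4,114.805887,2.965243,0.00087009
He,2,4,147.36126,2.458928,0.00070147
He,2,4,189.148322,2.039067,0.00056749
He,2,4,242.784892,1.690897,0.00046052
He,2,4,311.631123,1.402177,0.00037473
He,2,4,400.0,1.162755,0.00030566
Li,3,7,1.0,207.197819,1.43472119
Li,3,7,1.283569,178.300966,0.96908675
Li,3,7,1.647549,152.15419,0.64664803
Li,3,7,2.114743,128.849688,0.42813481
Li,3,7,2.714418,108.404606,0.28278825
Li,3,7,3.484142,90.734998,0.18740446
Li,3,7,4.472136,75.661054,0.12524648
Li,3,7,5.740294,62.933374,0.08475219
Li,3,7,7.368063,52.266944,0.05821799
Li,3,7,9.457416,43.372008,0.04064575
Li,3,7,12.139245,35.976073,0.02884561
Li,3,7,15.581556,29.836026,0.02079604
Li,3,7,20.0,24.742252,0.01521462
Li,3,7,25.671377,20.517674,0.0112819
Li,3,7,32.950979,17.014315,0.00846822
Li,3,7,42.294851,14.109129,0.00642628
Li,3,7,54.288352,11.7,0.00492488
Li,3,7,69.682838,9.702228,0.00380765
Li,3,7,89.442719,8.045575,0.00296719
Li,3,7,114.805887,6.671796,0.00232864
Li,3,7,147.36126,5.532588,0.00183913
Li,3,7,189.148322,4.5879,0.00146078
Li,3,7,242.784892,3.804518,0.00116617
Li,3,7,311.631123,3.154897,0.00093521
Li,3,7,400.0,2.6162,0.00075303
Be,4,9,1.0,338.594308,5.44977228
Be,4,9,1.283569,296.540974,3.77509252
Be,4,9,1.647549,257.110311,2.55655874
Be,4,9,2.114743,220.753787,1.69721627
Be,4,9,2.714418,187.854484,1.10957793
Be,4,9,3.484142,158.640443,0.71858163
Be,4,9,4.472136,133.149755,0.46398987
Be,4,9,5.740294,111.24266,0.3006059
Be,4,9,7.368063,92.644262,0.19648263
Be,4,9,9.457416,76.998768,0.1301115
Be,4,9,12.139245,63.920098,0.0875332
Be,4,9,15.581556,53.030263,0.05991115
Be,4,9,20.0,43.983093,0.04173064
Be,4,9,25.671377,36.47513,0.02956719
Be,4,9,32.950979,30.247523,0.02128908
Be,4,9,42.294851,25.082872,0.01555853
Be,4,9,54.288352,20.799996,0.01152595
Be,4,9,69.682838,17.248405,0.00864406
Be,4,9,89.442719,14.303245,0.00655473
Be,4,9,114.805887,11.86097,0.0050199
Be,4,9,147.36126,9.835713,0.00387875
Be,4,9,189.148322,8.156268,0.00302094
Be,4,9,242.784892,6.763587,0.00236967
Be,4,9,311.631123,5.608706,0.0018707
Be,4,9,400.0,4.651021,0.00148527
B,5,11,1.0,485.762375,15.09439731
B,5,11,1.283569,431.778684,10.79433392
B,5,11,1.647549,379.65508,7.50677902
B,5,11,2.114743,330.188397,5.08168006
B,5,11,2.714418,284.181551,3.35862168
B,5,11,3.484142,242.28668,2.17756748
B,5,11,4.472136,204.908282,1.39327517
B,5,11,5.740294,172.17396,0.88559287
B,5,11,7.368063,143.96095,0.56290908
B,5,11,9.457416,119.956815,0.35996462
B,5,11,12.139245,99.732099,0.23272525
B,5,11,15.581556,82.807681,0.15267199
B,5,11,20.0,68.706665,0.10185754
B,5,11,25.671377,56.987544,0.06918542
B,5,11,32.950979,47.260543,0.04785053
B,5,11,42.294851,39.191724,0.03368084
B,5,11,54.288352,32.499945,0.02410395
B,5,11,69.682838,26.950626,0.01751788
B,5,11,89.442719,22.34882,0.01291204
B,5,11,114.805887,18.532766,0.00963952
B,5,11,147.36126,15.368301,0.0072797
B,5,11,189.148322,12.744168,0.00555467
B,5,11,242.784892,10.568105,0.00427785
B,5,11,311.631123,8.763604,0.00332197
B,5,11,400.0,7.267221,0.00259893
C,6,12,1.0,643.636696,33.92028367
C,6,12,1.283569,579.267779,25.01681528
C,6,12,1.647549,515.560718,17.89745204
C,6,12,2.114743,453.585754,12.41570613
C,6,12,2.714418,394.544045,8.36507519
C,6,12,3.484142,339.546011,5.49254126
C,6,12,4.472136,289.445969,3.5320214
C,6,12,5.740294,244.755102,2.23785891
C,6,12,7.368063,205.630328,1.40625775
C,6,12,9.457416,171.920791,0.88225104
C,6,12,12.139245,143.247564,0.55598321
C,6,12,15.581556,119.093097,0.35375979
C,6,12,20.0,98.882202,0.22816332
C,6,12,25.671377,82.043756,0.14956919
C,6,12,32.950979,68.049817,0.09980849
C,6,12,42.294851,56.434701,0.06783892
C,6,12,54.288352,46.79961,0.04695869
C,6,12,69.682838,38.80884,0.03308179
C,6,12,89.442719,32.18229,0.02369494
C,6,12,114.805887,26.687181,0.0172339
C,6,12,147.36126,22.130353,0.01271165
C,6,12,189.148322,18.351602,0.00949594
C,6,12,242.784892,15.218071,0.00717536
C,6,12,311.631123,12.61959,0.00547786
C,6,12,400.0,10.464798,0.00422063
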