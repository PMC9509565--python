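p_value	t
1.5212960179e-01	1.45317954
4.0851833726e-01	-0.83318369
6.4807111204e-01	-0.45908291
9.1016658615e-01	-0.11337426
4.1595307010e-01	0.81995229
4.0149267070e-02	-2.10443366
9.2560459252e-01	-0.09382626
4.4030507239e-01	0.77758691
2.0216262599e-01	1.29158407
1.3854378926e-01	-1.50413310
2.4587290706e-01	-1.17355685
4.3653756927e-01	-0.78404818
1.0998038766e-03	3.45438133
8.3366592554e-01	-0.21104998
6.3991374895e-04	3.63171262
4.2323052362e-01	0.80713922
3.7128987483e-04	3.80580419
5.8346944849e-04	3.66152211
9.4740190590e-01	-0.06628623
4.4766878797e-01	-0.76505154
2.9661505881e-01	1.05421598
1.3469188580e-01	-1.51929650
2.4424731475e-03	3.18421151
3.1697233324e-01	-1.01033428
3.4073233508e-01	-0.96145829
2.2403638802e-01	1.23039828
7.1575930747e-01	-0.36610452
5.7111197180e-01	-0.56999809
8.2333922999e-01	-0.22437223
3.2133147543e-01	1.00118803
6.0676516155e-01	0.51781352
2.3534036954e-01	1.20049337
1.9898878150e-01	1.30086710
3.8716906343e-05	-4.49482208
3.8430128493e-04	3.79490116
9.6889026880e-01	-0.03918671
1.5347921815e-01	1.44831576
3.1978273863e-01	1.00442793
4.2901508408e-01	0.79704901
4.3811065090e-01	0.78134635
7.8685693214e-01	-0.27178121
7.1436383422e-02	1.83994606
3.4065439846e-01	0.96161485
1.2414520731e-04	4.14565937
7.8024774207e-01	-0.28043361
3.0870772556e-01	1.02791093
6.4146085094e-01	-0.46836910
7.8858615464e-01	0.26952085
9.6213414939e-01	0.04770291
5.5410898966e-01	-0.59544062
3.0829258076e-01	1.02880221
8.3155815804e-01	0.21376599
6.7559074233e-01	-0.42084025
2.2781977556e-01	-1.22026868
3.0793239213e-01	-1.02957617
1.2965535583e-03	-3.39957880
9.0464032270e-01	-0.12038210
8.8092628173e-01	0.15052678
6.3237529094e-01	-0.48120005
5.6140842649e-01	-0.58447119
9.8786025652e-01	-0.01528819
8.7982735336e-01	-0.15192688
5.9558888459e-01	0.53401196
9.8704563360e-01	0.01631418
5.2925647627e-01	-0.63335011
5.0646422574e-01	0.66894405
6.0334724222e-01	0.52275251
1.9973419919e-03	-3.25344760
9.5560686886e-01	-0.05593399
3.3671829492e-01	-0.96955266
1.7173238170e-01	1.38559737
8.2471017656e-02	-1.77039813
5.8136824237e-01	0.55483085
2.7769851278e-01	-1.09689068
5.1344469618e-02	1.99415093
4.0543580286e-02	-2.10011904
2.4363393303e-01	-1.17921198
1.7226291368e-01	-1.38385324
2.4385893544e-01	1.17864198
8.3140899968e-01	0.21395825
7.5325896422e-01	0.31599645
1.8144843349e-04	4.02935465
9.5736521766e-01	-0.05371631
7.3257791610e-01	0.34352303
2.7058350992e-06	-5.25958714
7.2089538065e-01	-0.35918897
3.3072143653e-03	3.07833787
8.0459155321e-01	0.24866401
4.4966909372e-01	-0.76166729
7.2310686942e-01	0.35621666
8.1263681060e-05	-4.27393679
8.5100681856e-01	0.18876309
8.6188404391e-01	0.17483274
1.9443536767e-01	-1.31438166
6.0166837036e-01	-0.52518326
2.0878333814e-02	-2.38200079
1.3831500354e-01	-1.50502433
6.8308715608e-01	0.41053262
7.9064726428e-01	0.26682848
4.5282594391e-01	0.75634413
7.1796167125e-01	-0.36313695
8.5865829315e-01	0.17896020
4.0004405017e-01	0.84844640
1.6740854822e-04	4.05415314
8.1797845320e-02	-1.77441040
9.3859644491e-01	0.07740421
2.1588718374e-05	-4.66605947
7.3431510991e-02	-1.82673276
8.4501924634e-01	0.19644709
2.5993095258e-01	-1.13887022
4.1848606050e-01	0.81547730
4.0691931430e-01	0.83604862
2.2257570597e-01	-1.23434275
7.7969095627e-01	-0.28116349
3.8411879831e-01	-0.87768061
9.8859210690e-01	0.01436647
9.7323188022e-01	0.03371561
2.6255268444e-03	3.15914290
9.0911367113e-01	-0.11470901
1.5962067929e-03	3.32968374
2.5977773958e-01	1.13924094
3.6785032406e-02	-2.14283159
3.7210619604e-01	-0.90024043
1.9186156691e-01	1.32212667
4.2136204132e-01	-0.81041618
2.9248445878e-04	-3.88093239
8.8932992999e-04	3.52446768
2.4321428262e-02	-2.31902185
9.4582805894e-01	0.06827275
5.6342772459e-01	-0.58144922
5.1374549282e-01	-0.65748193
1.9608543064e-01	-1.30945698
2.2139188757e-04	-3.96780213
8.5857938791e-01	-0.17906120
2.5564466939e-01	-1.14930069
7.5940000836e-01	0.30787031
9.0211820929e-01	0.12358236
2.9702468794e-01	1.05331300
2.3578146855e-09	-7.18929942
2.2114920307e-01	-1.23821335
9.6607377996e-01	-0.04273655
5.7059024888e-01	0.57077316
1.4847699903e-05	-4.77467066
2.1230800986e-01	1.26262345
1.1561821491e-02	-2.61703467
2.7015766111e-01	-1.11446882
4.2154981228e-01	-0.81008647
4.3967792232e-01	0.77866020
7.8319089951e-01	-0.27657799
4.1195892178e-01	-0.82704247
8.5779197463e-05	4.25765414
3.7996515625e-01	0.88543000
3.4688373851e-01	-0.94917486
5.0783017304e-01	0.66678705
1.4782857858e-02	2.52089090
8.5743587191e-01	0.18052514
5.7032524101e-01	0.57116699
2.9218864094e-02	-2.24193385
8.7206333661e-01	-0.16182750
5.7104192403e-01	-0.57010213
6.2983717829e-01	-0.48479878
4.5652624195e-01	0.75013197
2.7994504138e-01	1.09171875
3.0303296124e-03	-3.10908147
1.7069527455e-03	3.30697033
3.3471096808e-01	0.97362441
4.6303279266e-04	-3.73564957
3.2781300848e-04	3.84510686
6.7514851095e-01	-0.42144973
1.6919610247e-06	-5.39119727
2.7350586225e-04	3.90193956
4.2862065430e-02	-2.07546549
3.9744512807e-01	-0.85316715
1.3040517390e-03	3.39765040
2.1436164783e-04	-3.97781367
6.2296347979e-01	-0.49457708
5.5616975556e-03	-2.89188966
8.0461551262e-01	0.24863287
9.7899602461e-01	0.02645346
6.9287589733e-01	0.39713921
4.5763224484e-05	4.44537348
3.1883573117e-01	-1.00641424
8.0670793694e-01	0.24591454
2.5772536178e-01	-1.14422197
5.8603783901e-01	0.54796815
9.6140760629e-02	1.69428320
9.6096083679e-01	0.04918223
6.1529526925e-01	0.50554258
2.0995723897e-01	1.26924044
6.1538111646e-03	2.85481238
8.1894579288e-02	-1.77383215
7.9163336331e-01	-0.26554107
7.5014832172e-01	-0.32012069
4.8588862664e-01	0.70182764
1.1859197259e-01	-1.58669189
4.2521629569e-01	-0.80366609
8.4041345430e-01	0.20236584
4.2626076006e-02	-2.07792107
2.2765466426e-01	-1.22070817
1.7931382259e-01	1.36105614
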