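mass_da,intensity
8288.0,50.292
8288.5,0.0
8289.0,256.169
8289.5,41.96
8290.0,0.0
8290.5,144.638
8291.0,521.6
8291.5,378.832
8292.0,0.0
8292.5,0.0
8293.0,0.0
8293.5,16.53
8294.0,0.0
8294.5,0.0
8295.0,0.0
8295.5,0.0
8296.0,0.0
8296.5,0.0
8297.0,164.652
8297.5,417.005
8298.0,0.0
8298.5,546.585
8299.0,0.0
8299.5,140.604
8300.0,361.388
8300.5,37.605
8301.0,0.0
8301.5,0.0
8302.0,0.0
8302.5,88.089
8303.0,0.0
8303.5,0.0
8304.0,0.0
8304.5,303.838
8305.0,530.224
8305.5,1899.626
8306.0,5151.88
8306.5,12934.253
8307.0,24574.817
8307.5,35897.249
8308.0,39496.374
8308.5,35905.446
8309.0,24799.577
8309.5,13298.631
8310.0,5519.305
8310.5,1633.11
8311.0,1037.632
8311.5,937.228
8312.0,1067.342
8312.5,1845.752
8313.0,4203.16
8313.5,9256.257
8314.0,18194.139
8314.5,26737.497
8315.0,29484.655
8315.5,26632.956
8316.0,18367.866
8316.5,10017.997
8317.0,3586.486
8317.5,1054.228
8318.0,165.405
8318.5,0.0
8319.0,927.991
8319.5,681.576
8320.0,2838.405
8320.5,6389.628
8321.0,12764.003
8321.5,18178.082
8322.0,20253.341
8322.5,16768.534
8323.0,12151.425
8323.5,6766.527
8324.0,3108.328
8324.5,631.977
8325.0,954.339
8325.5,0.0
8326.0,0.0
8326.5,814.191
8327.0,1373.049
8327.5,4047.487
8328.0,6140.715
8328.5,8571.691
8329.0,9848.975
8329.5,8388.511
8330.0,5554.235
8330.5,3498.689
8331.0,1585.819
8331.5,957.193
8332.0,0.0
8332.5,697.518
8333.0,0.0
8333.5,630.164
8334.0,0.0
8334.5,0.0
8335.0,99.914
8335.5,412.581
8336.0,64.404
8336.5,0.0
8337.0,0.0
8337.5,0.0
8338.0,201.073
8338.5,395.885
8339.0,0.0
8339.5,0.0
8340.0,349.217
8340.5,0.0
8341.0,0.0
8341.5,248.407
8342.0,0.0
8342.5,154.548
8343.0,0.0
8343.5,43.712
8344.0,0.0
8344.5,80.846
8345.0,277.669
8345.5,0.0
8346.0,568.393
8346.5,290.438
8347.0,337.493
8347.5,465.946
8348.0,315.035
8348.5,337.631
8349.0,30.237
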