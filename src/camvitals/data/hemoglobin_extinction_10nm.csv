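wavelength_nm,eps_hbo2_cm1_M,eps_hbr_cm1_M
400,266232,223296
410,466840,303956
420,480360,407560
430,246072,528600
440,102580,413280
450,62816,103292
460,44480,41968
470,33209,22341
480,26629,16156
490,23684,18200
500,20932,20862
510,20035,25773
520,24202,30494
530,39956,39036
540,53236,46592
550,43016,52276
560,32613,53412
570,44496,44676
580,50104,27000
590,14400,18000
600,3200,14677
610,1506,11083
620,942,8819
630,610,7553
640,442,5149
650,368,3750
660,320,3227
670,294,2795
680,278,2407
690,276,2051
700,290,1794
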