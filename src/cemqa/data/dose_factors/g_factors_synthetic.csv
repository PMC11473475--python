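# Synthetic representative g-factor grid, version 1.0.
# g(HVL, thickness): conversion from incident air kerma to MGD for a 50%-glandular breast.
# These are NOT published values: they are a smooth surrogate surface with the correct
# qualitative structure (g increases with HVL, decreases with breast thickness) for
# pipeline development and testing. For absolute dosimetry replace this file with a
# transcription of a published factor table using the same columns.
hvl_mm_al,thickness_mm,g
0.3,20.0,0.375534
0.3,30.0,0.313672
0.3,40.0,0.262001
0.3,50.0,0.218842
0.3,60.0,0.182792
0.3,70.0,0.152681
0.3,80.0,0.12753
0.3,90.0,0.106522
0.3,100.0,0.088974
0.3,110.0,0.074318
0.4,20.0,0.46378
0.4,30.0,0.387382
0.4,40.0,0.323568
0.4,50.0,0.270267
0.4,60.0,0.225746
0.4,70.0,0.188559
0.4,80.0,0.157498
0.4,90.0,0.131553
0.4,100.0,0.109882
0.4,110.0,0.091781
0.5,20.0,0.53823
0.5,30.0,0.449567
0.5,40.0,0.37551
0.5,50.0,0.313653
0.5,60.0,0.261985
0.5,70.0,0.218828
0.5,80.0,0.18278
0.5,90.0,0.152671
0.5,100.0,0.127522
0.5,110.0,0.106515
0.6,20.0,0.601041
0.6,30.0,0.502031
0.6,40.0,0.419332
0.6,50.0,0.350255
0.6,60.0,0.292558
0.6,70.0,0.244365
0.6,80.0,0.204111
0.6,90.0,0.170488
0.6,100.0,0.142403
0.6,110.0,0.118945
0.8,20.0,0.698739
0.8,30.0,0.583636
0.8,40.0,0.487494
0.8,50.0,0.407189
0.8,60.0,0.340113
0.8,70.0,0.284086
0.8,80.0,0.237289
0.8,90.0,0.1982
0.8,100.0,0.165551
0.8,110.0,0.13828
1.0,20.0,0.768277
1.0,30.0,0.641719
1.0,40.0,0.536009
1.0,50.0,0.447712
1.0,60.0,0.373961
1.0,70.0,0.312358
1.0,80.0,0.260904
1.0,90.0,0.217925
1.0,100.0,0.182026
1.0,110.0,0.152041
1.5,20.0,0.866603
1.5,30.0,0.723848
1.5,40.0,0.604609
1.5,50.0,0.505012
1.5,60.0,0.421821
1.5,70.0,0.352335
1.5,80.0,0.294295
1.5,90.0,0.245815
1.5,100.0,0.205322
1.5,110.0,0.1715
2.0,20.0,0.908629
2.0,30.0,0.758951
2.0,40.0,0.633929
2.0,50.0,0.529502
2.0,60.0,0.442277
2.0,70.0,0.369421
2.0,80.0,0.308566
2.0,90.0,0.257736
2.0,100.0,0.215279
2.0,110.0,0.179817
2.5,20.0,0.926592
2.5,30.0,0.773954
2.5,40.0,0.646461
2.5,50.0,0.53997
2.5,60.0,0.451021
2.5,70.0,0.376724
2.5,80.0,0.314666
2.5,90.0,0.262831
2.5,100.0,0.219535
2.5,110.0,0.183371
3.0,20.0,0.934269
3.0,30.0,0.780367
3.0,40.0,0.651817
3.0,50.0,0.544444
3.0,60.0,0.454758
3.0,70.0,0.379845
3.0,80.0,0.317274
3.0,90.0,0.265009
3.0,100.0,0.221354
3.0,110.0,0.184891
3.5,20.0,0.937551
3.5,30.0,0.783108
3.5,40.0,0.654107
3.5,50.0,0.546356
3.5,60.0,0.456355
3.5,70.0,0.38118
3.5,80.0,0.318388
3.5,90.0,0.26594
3.5,100.0,0.222132
3.5,110.0,0.18554
4.0,20.0,0.938953
4.0,30.0,0.78428
4.0,40.0,0.655085
4.0,50.0,0.547173
4.0,60.0,0.457038
4.0,70.0,0.38175
4.0,80.0,0.318864
4.0,90.0,0.266338
4.0,100.0,0.222464
4.0,110.0,0.185818
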