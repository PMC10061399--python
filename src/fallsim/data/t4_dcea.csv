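row,column,value
mean_nhb,uc,4.1774
mean_nhb,rc,4.2081
mean_nhb,incremental,0.0307
atkinson_0,uc,4.1774
atkinson_0,rc,4.2081
atkinson_0,incremental,0.0307
atkinson_3,uc,3.9184
atkinson_3,rc,3.9521
atkinson_3,incremental,0.0337
atkinson_5,uc,3.7365
atkinson_5,rc,3.7722
atkinson_5,incremental,0.0357
atkinson_11,uc,3.3627
atkinson_11,rc,3.3994
atkinson_11,incremental,0.0367
atkinson_15,uc,3.2445
atkinson_15,rc,3.2804
atkinson_15,incremental,0.0359
atkinson_20,uc,3.1630
atkinson_20,rc,3.1981
atkinson_20,incremental,0.0351
atkinson_25,uc,3.1155
atkinson_25,rc,3.1501
atkinson_25,incremental,0.0346
atkinson_30,uc,3.0846
atkinson_30,rc,3.1189
atkinson_30,incremental,0.0343
kolm_0.025,uc,4.1698
kolm_0.025,rc,4.2005
kolm_0.025,incremental,0.0307
kolm_0.05,uc,4.1622
kolm_0.05,rc,4.1929
kolm_0.05,incremental,0.0307
kolm_0.15,uc,4.1311
kolm_0.15,rc,4.1618
kolm_0.15,incremental,0.0308
kolm_0.25,uc,4.0991
kolm_0.25,rc,4.1300
kolm_0.25,incremental,0.0309
kolm_0.4,uc,4.0501
kolm_0.4,rc,4.0810
kolm_0.4,incremental,0.0310
kolm_0.5,uc,4.0167
kolm_0.5,rc,4.0478
kolm_0.5,incremental,0.0311
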