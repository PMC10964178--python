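id,domain,path,mask_path,pathology_label,seed
00000,oct,images/00000_oct.png,masks/00000_mask.png,0,1026816910
00001,he,images/00001_he.png,masks/00001_mask.png,0,1083509134
00002,oct,images/00002_oct.png,,1,1251001413
00003,he,images/00003_he.png,,1,1188626511
00004,oct,images/00004_oct.png,masks/00004_mask.png,1,1094029748
00005,he,images/00005_he.png,,1,2137820579
00006,oct,images/00006_oct.png,,0,1734444720
00007,he,images/00007_he.png,masks/00007_mask.png,1,1702228508
00008,oct,images/00008_oct.png,,0,1503827930
00009,he,images/00009_he.png,,0,1336119720
00010,oct,images/00010_oct.png,,0,732347574
00011,he,images/00011_he.png,,0,2123775744
00012,oct,images/00012_oct.png,masks/00012_mask.png,0,1001222388
00013,he,images/00013_he.png,masks/00013_mask.png,1,462371908
00014,oct,images/00014_oct.png,masks/00014_mask.png,0,1814811279
00015,he,images/00015_he.png,masks/00015_mask.png,1,344052722
00016,oct,images/00016_oct.png,masks/00016_mask.png,1,1841358261
00017,he,images/00017_he.png,,0,1315418782
00018,oct,images/00018_oct.png,masks/00018_mask.png,0,246345229
00019,he,images/00019_he.png,,0,94364743
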