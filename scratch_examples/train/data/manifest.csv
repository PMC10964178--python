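id,domain,path,mask_path,pathology_label,seed
00000,oct,images/00000_oct.png,,0,1660599732
00001,he,images/00001_he.png,,1,1018936729
00002,oct,images/00002_oct.png,masks/00002_mask.png,1,65167554
00003,he,images/00003_he.png,,0,546351935
00004,oct,images/00004_oct.png,masks/00004_mask.png,0,1518195981
00005,he,images/00005_he.png,masks/00005_mask.png,0,1116052370
00006,oct,images/00006_oct.png,masks/00006_mask.png,1,803682512
00007,he,images/00007_he.png,,0,544698542
00008,oct,images/00008_oct.png,,0,195104716
00009,he,images/00009_he.png,masks/00009_mask.png,0,1306965658
00010,oct,images/00010_oct.png,masks/00010_mask.png,0,1418413093
00011,he,images/00011_he.png,,1,1117147995
00012,oct,images/00012_oct.png,masks/00012_mask.png,1,2000303395
00013,he,images/00013_he.png,masks/00013_mask.png,0,1992734994
00014,oct,images/00014_oct.png,,1,444939644
00015,he,images/00015_he.png,masks/00015_mask.png,0,1306001769
00016,oct,images/00016_oct.png,,0,1353108399
00017,he,images/00017_he.png,,1,532409422
00018,oct,images/00018_oct.png,,1,640300361
00019,he,images/00019_he.png,masks/00019_mask.png,1,1046488572
00020,oct,images/00020_oct.png,,0,1592910340
00021,he,images/00021_he.png,masks/00021_mask.png,1,628159279
00022,oct,images/00022_oct.png,,0,1550837115
00023,he,images/00023_he.png,masks/00023_mask.png,1,1403962284
00024,oct,images/00024_oct.png,,1,469687797
00025,he,images/00025_he.png,masks/00025_mask.png,1,832869877
00026,oct,images/00026_oct.png,,0,1782168491
00027,he,images/00027_he.png,,0,1809631772
00028,oct,images/00028_oct.png,,0,1412297367
00029,he,images/00029_he.png,,0,10139966
00030,oct,images/00030_oct.png,masks/00030_mask.png,0,1466299488
00031,he,images/00031_he.png,,0,483430030
00032,oct,images/00032_oct.png,masks/00032_mask.png,1,1761099262
00033,he,images/00033_he.png,masks/00033_mask.png,1,1962009842
00034,oct,images/00034_oct.png,,0,920353303
00035,he,images/00035_he.png,,0,2055089921
00036,oct,images/00036_oct.png,masks/00036_mask.png,1,1629307570
00037,he,images/00037_he.png,masks/00037_mask.png,0,699224024
00038,oct,images/00038_oct.png,masks/00038_mask.png,0,1886521830
00039,he,images/00039_he.png,masks/00039_mask.png,0,825886284
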