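mpa_id,designation,center_lon,center_lat,area_km2,Acropora solitaryensis,Apostichopus japonicus,Epinephelus akaara,Epinephelus bruneus,Nemipterus virgatus,Scomberomorus niphonius,Argyrosomus japonicus,Larimichthys crocea,Evynnis cardinalis,Portunus Trituberculatus,Anguilla japonica,Argyrosomus argentatus,Sepiella maindroni,Penaeus japonicus
JS-1,MNR,121.7414,35.6,514.55,0,0,0,0,0,0,0,1,1,1,1,1,1,1
JS-2,MNR,121.7277,35.0,2472.6,0,0,0,0,0,0,1,1,1,1,1,1,1,1
JS-3,SMPA,121.4418,34.5,780.0,0,0,0,0,0,0,0,1,1,1,1,1,1,1
JS-4,SMPA,121.1019,33.8,47.1,0,0,0,0,0,0,0,1,1,1,1,1,1,1
JS-5,SMPA,120.8738,33.1,15.46,0,0,0,0,0,0,0,1,1,1,1,1,1,1
SH-1,MNR,120.4925,31.6,241.55,0,0,0,0,0,0,0,0,1,1,1,1,1,1
SH-2,SMPA,120.4019,31.2,423.2,0,0,0,0,0,0,0,0,1,1,1,1,1,1
ZJ-1,MNR,120.238,30.6,549.0,0,1,1,1,1,1,1,1,1,1,1,1,1,1
ZJ-2,SMPA,120.0667,30.2,218.4,0,1,1,1,1,1,1,1,1,1,1,1,1,1
ZJ-3,SMPA,119.9886,29.8,484.78,0,0,0,0,1,1,1,1,1,1,1,1,1,1
ZJ-4,SMPA,119.7787,29.4,44.19,0,0,0,0,1,1,1,1,1,1,1,1,1,1
ZJ-5,MNR,119.6637,29.0,57.0,0,1,1,1,1,1,1,1,1,1,1,1,1,1
ZJ-6,SMPA,119.532,28.6,30.8,0,0,0,0,1,1,1,1,1,1,1,1,1,1
ZJ-7,SMPA,119.4807,28.2,306.69,0,0,1,1,1,1,1,1,1,1,1,1,1,1
ZJ-8,SMPA,119.361,27.8,311.04,0,0,1,1,1,1,1,1,1,1,1,1,1,1
ZJ-9,MNR,119.2209,27.4,201.06,0,1,1,1,1,1,1,1,1,1,1,1,1,1
FJ-1,SMPA,119.0068,26.8,67.83,0,0,1,1,1,1,1,1,1,1,1,1,1,1
FJ-2,SMPA,118.8369,26.3,22.6,0,0,1,1,1,1,1,1,1,1,1,1,1,1
FJ-3,SMPA,118.6878,25.8,24.44,0,0,1,1,1,1,1,1,1,1,1,1,1,1
FJ-4,MNR,118.5131,25.2,34.9,1,1,1,1,1,1,1,1,1,1,1,1,1,1
FJ-5,SMPA,118.3463,24.6,69.11,1,0,1,1,1,1,1,1,1,1,1,1,1,1
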