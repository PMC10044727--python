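name,taxon_class,category,pld_days,living_depth_m,spawn_start_month,spawn_end_month
Nemipterus virgatus,Actinopterygii,threatened,75,25,4,5
Sepiella maindroni,Cephalopoda,economic,45,10,4,5
Epinephelus bruneus,Actinopterygii,threatened,45,20,5,6
Larimichthys crocea,Actinopterygii,threatened,33,15,4,5
Argyrosomus argentatus,Actinopterygii,economic,33,50,6,8
Argyrosomus japonicus,Actinopterygii,threatened,33,100,1,3
Evynnis cardinalis,Actinopterygii,threatened,30,45,11,1
Apostichopus japonicus,Holothuroidea,threatened,20,10,5,6
Scomberomorus niphonius,Actinopterygii,economic,19,20,5,6
Portunus Trituberculatus,Malacostraca,economic,17,20,4,6
Epinephelus akaara,Actinopterygii,threatened,15,25,4,6
Anguilla japonica,Actinopterygii,threatened,10,3,11,12
Penaeus japonicus,Crustacea,economic,10,20,12,3
Acropora solitaryensis,Anthozoa,threatened,7,5,4,5
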