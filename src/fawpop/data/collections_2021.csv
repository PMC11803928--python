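county,state,flyway,month,host,n,n_c,n_hybrid,n_r
Hidalgo,TX,Central,March,Sorghum,16,5,0,11
Hidalgo,TX,Central,June,Sorghum,17,10,0,7
Hidalgo,TX,Central,October,Maize,17,3,0,14
Lubbock,TX,Central,October,Mixed agriculture,21,13,0,8
Tazewell,IL,Central,August,Maize,16,0,0,16
Tazewell,IL,Central,September,Mixed grasses,5,0,0,5
Larimer,CO,Central,September,Mixed agriculture,19,17,0,2
Centre,PA,Central,August,Mixed agriculture,17,3,0,14
Miami-Dade,FL,Eastern,March,Maize,12,4,0,8
Palm Beach,FL,Eastern,March,Mixed agriculture,27,9,3,15
Palm Beach,FL,Eastern,September,Mixed agriculture,17,7,0,10
Palm Beach,FL,Eastern,October,Mixed agriculture,22,4,2,16
Palm Beach,FL,Eastern,November,Mixed agriculture,19,3,0,16
Duval,FL,Eastern,October,Mixed grasses,15,3,0,12
Burke,GA,Eastern,September,Mixed agriculture,19,1,0,18
Burke,GA,Eastern,October,Mixed agriculture,18,17,0,1
Pike,GA,Eastern,July,Maize,12,0,2,10
Juana Diaz,PR,Eastern,March,Maize,21,20,1,0
Pinal,AZ,Western,September,Alfalfa,10,10,0,0
Pinal,AZ,Western,September,Maize,10,10,0,0
Yuma,AZ,Western,September,Mixed agriculture,21,21,0,0
Kern,CA,Western,June,Mixed grasses,16,15,1,0
Kern,CA,Western,August,Mixed grasses,23,23,0,0
Kern,CA,Western,September,Mixed grasses,22,22,0,0
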