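municipality,n_crops,gdp_usd,cpv_usd,main_crop,main_crop_pct,psv_usd,pct_gdp
Igarapé Miri,14,91838500,460555250,Açaí,99,298143775,324.64
Medicilândia,18,141450000,86838500,Cocoa (almond),86,72107363,50.98
Abaetetuba,18,312313750,168501250,Açaí,97,106839000,34.21
Muaná,7,58894000,21906500,Açaí,99,14170338,24.06
Placas,15,65144500,27122000,Cocoa (almond),51,13542738,20.79
São Sebastião da Boa Vista,2,44696500,13019000,Açaí,99,8450000,18.91
Uruará,17,125868750,30064500,Cocoa (almond),65,20167738,16.02
Brasil Novo,16,57163250,11527500,Cocoa (almond),75,8294363,14.51
Inhangapi,13,27833000,9536250,Açaí,54,3761625,13.51
Moju,18,217053750,74713000,Açaí,52,28025688,12.91
Bujaru,11,122488500,30928000,Açaí,73,14905550,12.17
Dom Eliseu,17,164022000,92037500,Soybean (grain),78,18733275,11.42
Mojuí dos Campos,20,34328250,17408250,Soybean (grain),53,3487988,10.16
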