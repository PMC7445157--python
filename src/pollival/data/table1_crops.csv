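crop,dependence_class,cpv_usd,psv_usd
Açaí,Great,977837000,635594050
Cocoa (almond),Essential,197486500,187612175
Soybean (grain),Modest,393745250,98436313
Watermelon,Essential,27441250,26069188
Orange,Modest,36856500,9214125
Passion fruit,Essential,9339000,8872050
Coco,Modest,27222500,6805625
Oil palm (coconut bunch),Little,95619500,4780975
Tomato,Great,4535250,2947913
Bean (grain),Little,20863250,1043163
Guava,Great,1425500,926575
Papaya,Little,6508750,325438
Cashew nut,Modest,874250,218563
Avocado,Great,245750,159738
Coffee (grain) Total,Modest,310250,77563
Annatto (seed),Little,1338500,66925
Guarana (seed),Great,56250,36563
Tangerine,Little,351500,17575
Melon,Essential,15250,14488
Peanuts (shell),Little,49500,2475
Manioc,No increase,483324000,0
Black pepper,No increase,209045500,0
Banana (bunch),No increase,167798500,0
Corn (grain),No increase,117626250,0
Pineapple,No increase,92205750,0
Rice (shell),No increase,37331000,0
Sugar cane,No increase,19398000,0
Brazilian Lemon,Unknown,17837500,
Palm heart,No increase,1203250,0
Sorghum (grain),No increase,1054000,0
Rubber (coagulated lathe),No increase,855250,0
Mallow (fiber),No increase,328750,0
Onion,No increase,157500,0
Mango,No increase,113000,0
Sweet potato,No increase,97000,0
Smoke (leaves),No increase,22750,0
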