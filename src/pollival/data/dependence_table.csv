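crop,dependence_class
Açaí,high
Cocoa (almond),essential
Soybean (grain),modest
Watermelon,essential
Orange,modest
Passion fruit,essential
Coco,modest
Oil palm (coconut bunch),little
Tomato,high
Bean (grain),little
Guava,high
Papaya,little
Cashew nut,modest
Avocado,high
Coffee (grain) Total,modest
Annatto (seed),little
Guarana (seed),high
Tangerine,little
Melon,essential
Peanuts (shell),little
Manioc,none
Black pepper,none
Banana (bunch),none
Corn (grain),none
Pineapple,none
Rice (shell),none
Sugar cane,none
Brazilian Lemon,unknown
Palm heart,none
Sorghum (grain),none
Rubber (coagulated lathe),none
Mallow (fiber),none
Onion,none
Mango,none
Sweet potato,none
Smoke (leaves),none
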