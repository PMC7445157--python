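microregion,cpv_usd,psv_usd
Cametá,750213500,438878787
Paragominas,358140500,68100837
Tomé-Açu,263353750,59193300
Altamira,200054000,130965162
Guamá,182894000,17619400
Santarém,182351000,30947475
Conceição do Araguaia,158425000,17922825
Tucuruí,118008250,22995137
Belém,103788000,65385875
Bragantina,94947750,4810475
Castanhal,90014750,27098812
Itaituba,87384750,13304412
São Felix do Xingu,71774000,21426175
Portel,46079750,14659025
Parauapebas,44496250,4373212
Óbidos,43582500,2129262
Arari,41718500,20267562
Redenção,38396000,4755012
Marabá,28876500,1899075
Salgado,23654750,5148512
Furos de Breves,19431750,10951112
Almeirim,5497000,1959237
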