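municipality_id,municipality_name,microregion_id,microregion_name
igarape-miri,Igarapé Miri,cameta,Cametá
abaetetuba,Abaetetuba,cameta,Cametá
medicilandia,Medicilândia,altamira,Altamira
uruara,Uruará,altamira,Altamira
brasil-novo,Brasil Novo,altamira,Altamira
muana,Muaná,arari,Arari
santa-cruz-do-arari,Santa Cruz do Arari,arari,Arari
placas,Placas,itaituba,Itaituba
sao-sebastiao-da-boa-vista,São Sebastião da Boa Vista,furos-de-breves,Furos de Breves
inhangapi,Inhangapi,castanhal,Castanhal
bujaru,Bujaru,castanhal,Castanhal
moju,Moju,tome-acu,Tomé-Açu
dom-eliseu,Dom Eliseu,paragominas,Paragominas
mojui-dos-campos,Mojuí dos Campos,santarem,Santarém
cameta-mun,Cametá,cameta,Cametá
paragominas-mun,Paragominas,paragominas,Paragominas
tome-acu-mun,Tomé-Açu,tome-acu,Tomé-Açu
altamira-mun,Altamira,altamira,Altamira
santarem-mun,Santarém,santarem,Santarém
conceicao-do-araguaia-mun,Conceição do Araguaia,conceicao-do-araguaia,Conceição do Araguaia
tucurui-mun,Tucuruí,tucurui,Tucuruí
belem-mun,Belém,belem,Belém
castanhal-mun,Castanhal,castanhal,Castanhal
itaituba-mun,Itaituba,itaituba,Itaituba
sao-felix-do-xingu-mun,São Felix do Xingu,sao-felix-do-xingu,São Felix do Xingu
portel-mun,Portel,portel,Portel
parauapebas-mun,Parauapebas,parauapebas,Parauapebas
obidos-mun,Óbidos,obidos,Óbidos
redencao-mun,Redenção,redencao,Redenção
maraba-mun,Marabá,maraba,Marabá
breves-mun,Breves,furos-de-breves,Furos de Breves
almeirim-mun,Almeirim,almeirim,Almeirim
braganca-mun,Bragança,bragantina,Bragantina
vigia-mun,Vigia,salgado,Salgado
ourem-mun,Ourém,guama,Guamá
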