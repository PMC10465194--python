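species,wintering_area,foraging_niche
Acrocephalus arundinaceus,Tropical,invertivore glean arboreal
Acrocephalus schoenobaenus,Sahel,invertivore glean arboreal
Anthus trivialis,Tropical,invertivore ground
Delichon urbica,Tropical,invertivore sally air
Erithacus rubecula,North Africa,invertivore ground
Ficedula albicollis,Tropical,invertivore sally air
Ficedula hypoleuca,Tropical,invertivore sally air
Fringilla coelebs,North Africa,invertivore ground
Hippolais icterina,Tropical,invertivore glean arboreal
Hirundo rustica,Sahel,invertivore sally air
Jynx torquilla,Sahel,invertivore ground
Lanius senator,Tropical,invertivore ground
Luscinia megarhynchos,Tropical,invertivore ground
Merops apiaster,Sahel,invertivore sally air
Muscicapa striata,Sahel,invertivore sally air
Oenanthe oenanthe,Sahel,invertivore sally ground
Oriolus oriolus,Tropical,omnivorous arboreal
Phoenicurus ochruros,North Africa,invertivore sally ground
Phoenicurus phoenicurus,Sahel,invertivore sally ground
Phylloscopus collybita,North Africa,invertivore glean arboreal
Phylloscopus sibilatrix,Tropical,invertivore glean arboreal
Phylloscopus trochilus,Sahel,invertivore glean arboreal
Saxicola rubetra,Tropical,invertivore sally ground
Saxicola torquata,North Africa,invertivore sally ground
Streptopelia turtur,Sahel,granivore ground
Sylvia atricapilla,North Africa,invertivore glean arboreal
Sylvia borin,Tropical,invertivore glean arboreal
Sylvia cantillans,Sahel,invertivore glean arboreal
Sylvia communis,Sahel,invertivore glean arboreal
Turdus philomelos,North Africa,invertivore ground
Upupa epops,Sahel,invertivore ground
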