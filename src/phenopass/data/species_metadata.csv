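species,wintering_group,dimorphic,median_passage_day,annual_captures,peak_trend_days_per_year
Acrocephalus arundinaceus,Tropical,False,124.2,23,-0.6
Acrocephalus schoenobaenus,Sahel,False,127.1,65,0.3
Anthus trivialis,Tropical,False,108.4,122,-0.5
Erithacus rubecula,North Africa,False,86.5,725,-1.0
Ficedula albicollis,Tropical,True,112.7,86,-0.4
Ficedula hypoleuca,Tropical,True,115.8,573,0.1
Hippolais icterina,Tropical,False,109.4,367,0.4
Hirundo rustica,Tropical,True,105.3,28,-0.5
Jynx torquilla,Sahel,False,121.0,38,-0.3
Lanius senator,Sahel,True,105.3,101,-0.2
Luscinia megarhynchos,Tropical,False,120.7,41,-0.4
Merops apiaster,Tropical,True,130.4,481,-0.1
Muscicapa striata,Sahel,False,134.3,1048,0.5
Oenanthe hispanica,Sahel,False,105.7,7,-1.2
Oenanthe oenanthe,Sahel,True,105.7,117,-0.7
Oriolus oriolus,Tropical,True,123.4,78,0.4
Phoenicurus ochruros,North Africa,False,83.1,110,-0.4
Phoenicurus phoenicurus,Sahel,True,110.4,304,-1.4
Phylloscopus collybita,North Africa,False,86.9,212,-1.3
Phylloscopus sibilatrix,Tropical,False,116.4,821,0.3
Phylloscopus trochilus,Sahel,False,110.0,704,-0.7
Saxicola rubetra,Tropical,True,119.5,943,0.1
Saxicola torquatus,North Africa,False,74.9,31,-0.4
Streptopelia turtur,Sahel,False,123.0,31,-0.1
Sylvia atricapilla,North Africa,True,98.4,128,-0.3
Sylvia borin,Tropical,False,130.2,2762,0.2
Sylvia cantillans,Sahel,True,97.2,446,-1.0
Sylvia communis,Sahel,False,121.3,1694,-0.1
Turdus philomelos,North Africa,False,82.8,102,-1.3
Upupa epops,Sahel,False,91.9,25,-1.1
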