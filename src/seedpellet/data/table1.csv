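species,provenance,growth_form,bare_emergence_pct,pellet_emergence_pct,bare_survival_pct,pellet_survival_pct,bare_mean_days,pellet_mean_days,bare_eri,pellet_eri,bare_tse_days,pellet_tse_days
Acacia decurrens,,shrub,100,70,100,66,14,25,3.57,0.49,0,16
Acacia falcata,1,shrub,94,48,100,80,23,35,0.73,0.14,16,27
Acacia falcata,2,shrub,90,30,98,96,20,32,0.6,0.11,24,42
Acacia implexa,,shrub,98,66,100,76,15,27,1.11,0.26,16,42
Acacia parramattensis,,shrub,94,60,100,67,15,22,1.59,0.46,8,24
Ajuga australis,,herb,66,22,97,100,36,34,0.16,0.06,94,36
Allocasuarina littoralis,,tree,88,66,100,100,21,34,0.46,0.21,43,49
Aristida vagans,,graminoid,30,22,73,64,21,27,0.2,0.13,27,78
Arthropodium milleflorum,,herb,88,48,100,79,32,48,0.22,0.08,42,120
Bothriochloa macera,,graminoid,54,58,93,90,17,21,0.53,0.39,13,64
Bursaria spinosa,,shrub,58,100,90,100,36,28,0.15,0.6,89,12
Carex inversa,,graminoid,50,98,96,82,48,35,0.08,0.21,65,41
Centella asiatica,,herb,30,82,80,73,38,34,0.08,0.27,78,34
Chenopodium nutans,,herb,6,42,67,76,17,34,0.09,0.12,8,113
Chenopodium trigonon,,herb,80,100,35,94,23,14,0.39,1.86,113,7
Chloris truncata,,graminoid,40,62,35,77,24,13,0.19,0.97,50,15
Chloris ventricosa,,graminoid,24,20,100,60,13,17,0.39,0.16,15,31
Coleus australis,,shrub,10,82,100,95,26,24,0.1,0.32,12,41
Commelina cyanea,,herb,24,52,92,96,20,24,0.21,0.28,20,27
Convolvulus erubescens,,shrub,40,16,90,100,8,15,1.37,0.51,23,64
Corymbia maculata,,tree,,4,,100,,69,,0.02,,51
Cymbopogon refractus,,graminoid,46,34,74,76,17,27,0.46,0.17,13,20
Daviesia ulicifolia,,shrub,58,62,100,45,31,37,0.25,0.14,29,105
Dillwynia sieberi,,shrub,96,72,100,78,27,49,0.33,0.12,43,105
Dodonaea viscosa,1,shrub,62,4,100,100,23,111,0.01,0.12,33,94
Dodonaea viscosa,2,shrub,28,4,84,100,35,30,0.12,0.06,94,0
Eremophila debilis,,herb,16,32,88,81,40,64,0.07,0.06,12,56
Eucalyptus amplifolia,,tree,84,100,95,100,20,10,0.51,2.81,105,8
Eucalyptus crebra,1,tree,78,86,97,88,10,19,1.28,0.66,36,80
Eucalyptus crebra,2,tree,100,100,98,100,16,15,0.83,0.89,36,23
Eucalyptus eugenioides,,tree,66,88,100,95,18,19,0.94,1.23,8,8
Eucalyptus longifolia,,tree,42,92,90,100,27,20,0.21,0.83,34,41
Eucalyptus moluccana,1,tree,86,82,100,95,14,14,0.92,0.84,57,36
Eucalyptus moluccana,2,tree,100,100,100,92,13,12,1.31,1.58,50,31
Eucalyptus punctata,,tree,86,44,93,100,25,34,0.58,0.25,12,33
Eucalyptus tereticornis,,tree,100,82,100,95,10,12,2.07,1.41,36,15
Fimbristylis dichotoma,,graminoid,32,98,44,59,36,26,0.12,0.97,26,12
Geranium solanderi,,herb,94,88,100,89,20,18,0.56,0.65,31,24
Glossocardia bidens,,herb,34,40,53,50,23,32,0.25,0.12,13,72
Hardenbergia violacea,,shrub,84,74,100,81,21,25,0.38,0.32,43,29
Hypericum gramineum,,herb,96,52,81,58,31,23,0.34,0.58,57,16
Indigofera australis,,shrub,82,20,71,70,12,16,1.05,0.19,23,23
Laxmannia gracilis,,herb,60,6,100,100,44,45,0.11,0.03,78,7
Lomandra longifolia,,graminoid,30,,73,,74,,0.07,,0.37,
Melaleuca decora,,shrub,38,100,84,86,39,28,0.14,0.98,56,56
Mentha satureioides,,herb,2,4,100,0,57,44,0.02,0.07,0,72
Microlaena stipoides,,graminoid,20,,60,,17,,0.3,,8,
Ozothamnus diosmifolius,,shrub,32,12,69,0,13,8,0.51,0.75,21,0
Panicum simile,,graminoid,4,20,50,40,22,31,0.09,0.09,0,49
Pentapogon micranthus,,graminoid,92,100,87,100,21,17,0.5,1,41,20
Phyllanthus virgatus,,herb,,8,,75,,47,,0.04,,7
Plantago gaudichaudii,,herb,52,94,96,100,21,13,0.3,1.34,72,16
Poa labillardierei,,graminoid,78,56,90,46,17,14,0.62,2,24,0
Pomax umbellata,,shrub,12,52,0,69,73,63,0.03,0.1,37,28
Sarga leioclada,,graminoid,8,4,75,100,19,33,0.11,0.04,13,34
Senecio quadridentatus,,herb,8,,75,,33,,0.04,,34,
Setaria distans,,graminoid,38,24,58,83,28,43,0.18,0.06,26,97
Solanum prinophyllum,,herb,74,80,95,88,19,26,0.7,0.33,16,29
Sporobolus creber,,graminoid,24,98,83,98,31,20,0.09,1.28,41,8
Syncarpia glomulifera,,tree,30,6,80,100,31,36,0.14,0.04,35,21
Themeda triandra,,graminoid,16,12,100,100,10,14,0.46,0.43,7,0
Wahlenbergia gracilis,,herb,86,54,72,37,33,22,0.25,0.61,57,8
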