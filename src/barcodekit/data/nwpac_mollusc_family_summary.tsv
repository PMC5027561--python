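family	species_barcoded	species_indistinguishable	species_deep_divergence	candidate_lineages
Veneridae	60	9	10	21
Trochidae	42	0	3	8
Muricidae	35	2	5	11
Mytilidae	26	3	3	9
Octopodidae	26	0	1	2
Lottiidae	23	3	2	5
Turbinidae	22	3	0	0
Littorinidae	19	0	3	6
Buccinidae	19	0	0	0
Sepiidae	19	0	1	2
Arcidae	19	0	5	11
Neritidae	14	0	2	4
Plakobranchidae	9	0	3	9
Gonatidae	9	0	0	0
Loliginidae	9	0	1	2
Mactridae	9	1	1	2
Nassariidae	9	1	1	2
Conidae	8	2	0	0
Ostreidae	8	0	2	4
Potamididae	8	0	2	5
Pectinidae	7	0	0	0
Nacellidae	7	0	2	4
Pteriidae	6	0	0	0
Polyceridae	6	0	0	0
Strombidae	6	0	0	0
Calliostomatidae	6	0	0	0
Corbiculidae	6	2	0	0
Psammobiidae	5	0	0	0
Isognomonidae	5	0	0	0
Sepiolidae	5	0	1	2
Tellinidae	4	0	1	2
Pholadidae	4	0	0	0
Cypraeidae	4	0	1	2
Acanthochitonidae	3	1	1	2
Aglajidae	3	0	0	0
Calliotropidae	3	0	0	0
Cardiidae	3	0	1	2
Cerithiidae	3	0	0	0
Colloniidae	3	0	0	0
Columbellidae	3	2	1	2
Ficidae	3	0	0	0
Fissurellidae	3	0	1	2
Lepetidae	3	0	0	0
Melongenidae	3	0	0	0
Neritiliidae	3	0	0	0
Onchidiidae	3	0	1	2
Tonnidae	3	0	0	0
Vesicomyidae	3	0	0	0
Naticidae	2	0	0	0
Solenidae	2	1	1	2
Aeolidiidae	2	0	0	0
Batillariidae	2	0	1	2
Bursidae	2	0	0	0
Cassidae	2	0	0	0
Corbulidae	2	0	0	0
Elysiidae	2	0	0	0
Glycymerididae	2	0	0	0
Idiosepiidae	2	1	0	0
Limapontiidae	2	0	0	0
Noetiidae	2	0	0	0
Patellidae	2	0	0	0
Semelidae	2	0	0	0
Skeneidae	2	0	0	0
Solecurtidae	2	0	0	0
Stomatellidae	2	0	0	0
Fasciolariidae	2	0	1	2
Turritellidae	1	0	0	0
Acmaeidae	1	0	0	0
Aplysiidae	1	0	0	0
Architeuthidae	1	0	0	0
Cavoliniidae	1	0	1	2
Cocculinidae	1	0	0	0
Clavatulidae	1	0	0	0
Cultellidae	1	0	1	2
Donacidae	1	0	0	0
Dorididae	1	0	0	0
Haminoeidae	1	0	0	0
Lepetodrilidae	1	0	0	0
Myidae	1	0	0	0
Personidae	1	0	0	0
Pharidae	1	0	1	2
Pinnidae	1	0	1	2
Planaxidae	1	0	0	0
Pleurotomariidae	1	0	0	0
Ranellidae	1	0	0	0
Siphonariidae	1	0	0	0
Terebridae	1	0	0	0
Turbinellidae	1	0	0	0
Turridae	1	0	0	0
Volutidae	1	0	0	0
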