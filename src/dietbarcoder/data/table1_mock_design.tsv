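species	taxon_group	MOCK-A	MOCK-B	MOCK-C	MOCK-D	tl_mm	sd_mm	otu
Meganyctiphanes norvegica	Euphausiid	101	33	1	100	8.7	2.0	Meganyctiphanes norvegica
Undeuchaeta major	Copepod	13	39	1	1	5.5	0.2	Para-Und-Euch group
Undeuchaeta plumosa	Copepod	3	9	1	1	4.5	0.2	Para-Und-Euch group
Euchirella rostrata	Copepod	20	60	1	1	3.7	0.1	Para-Und-Euch group
Euchirella curticauda	Copepod	2	6	1	1	4.6	0.3	Para-Und-Euch group
Paraeuchaeta gracilis	Copepod	22	66	1	1	7.3	0.5	Para-Und-Euch group
Paraeuchaeta tonsa/pseudotonsa	Copepod	12	36	1	1	5.4	0.3	Para-Und-Euch group
Euchaeta hebes	Copepod	15	45	1	1	3.3	0.2	Para-Und-Euch group
Euchaeta acuta	Copepod	3	9	1	1	3.7	0.2	Para-Und-Euch group
Pleuromamma robusta	Copepod	23	69	1	1	4.1	0.3	Pleuromamma robusta
Candacia armata	Copepod	10	30	1	1	2.9	0.2	Candacia armata
Calanus helgolandicus	Copepod	7	21	1	1	3.0	0.2	Calanus helgolandicus
Tomopteris spp.	Polychaeta	25	80	1	1	7.6	1.1	Tomopteris spp.
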