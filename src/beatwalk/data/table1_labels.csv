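song_id,performer,title,label
1,Mr. de Sainte-Colombe,Courante,r1
2,Hector Zazou,Eye Spy,r2
3,S.E.S.,Sad Song,r3
4,Manu Chao,Minha galera,r4
5,Willem Vermandere,Schoorbakkebrug,r5
6,Penguin Cafe Orchestra,Paul's Dance,r6
7,Al Dexter,Guitar Polka,r7
8,Ken Boothe,Archibella,r8
9,Joseph Haydn,Simphonietta,r9
10,Django Reinhardt,It don't mean a thing,r10
11,Tokyo's Coolest Combo,Comment te dire adieu,
12,CPEX,Pinocchio,
13,Bruce Channel,Hey Baby (Dirty Dancing),
14,Will Tura,Hopeloos,
15,Antonello Paliotti,Sotto e'ncoppa,
16,Rosalie Allen,I wanna be a cowboy sweetheart,
17,Moving Hearts,Hiroshima Nagasaki Russian Roulette,
18,Amuka,Appreciate me,
19,France Gall,Laisse tomber les filles,
20,Nathalie McMaster,Capers jigs,
21,Santana,Primavera,
22,Charles Dieupart,"Concerto in a-minor, allegro",
23,Joseph Bodin de Boismortier,"Don Quichotte chez la Duchesse, Tambourin I",
24,Antonio Vivaldi,"Cello Sonata in a-minor, allegro",
25,Georg Friedrich Handel,"Allegro Trio Sonata in g-minor, allegro",
26,traditional Irish,Fred's tune,
27,anonymous,la Rotta,
28,Suksinder Shinda,Punjabain,
29,Elysium,Interpretation of Dreams,
30,Banda 11 de Enero,Feria de Manizales,
31,Pena Suazo y su Banda Gorda,"Aqui, pero alla",
32,Jovanotti,Tutto l'Amore Che Ho,
33,Date of Birth,Aim at El Paso,
34,O-zone,Dragosta din tei,
35,Communards,Don't leave me this way,
36,Boredoms Jungle,Taitei,
37,Van Halen,Dance the night away,
38,Vasmolon,Lard Ki Labam,
39,Kieran Fahy,McHugh's,
40,Kosheen,Catch,
41,Jefferson Airplane,Somebody to love,
42,Matthew Dekay,If I could fly,
43,Aqua,Barbie Girl,a10
44,tatu,Not gonna get us,a9
45,Traffic Signs,The big fake,a8
46,Le grand rouge,Parlens d'aimer,a7
47,Junior Jack,The hype,a6
48,Peter Katafalk,Down and Out,a5
49,Kujay Dada,Young Hearts,a4
50,Franceso Veracini,"Ouverture no.5 (b-major), allegro",a3
51,Clawfinger,Out to get me,a2
52,Falik,The ballad of El Efe,a1
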