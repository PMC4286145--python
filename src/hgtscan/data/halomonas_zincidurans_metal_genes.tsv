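gene_id	position_start	position_end	size_aa	strand	product	organism	taxon_class	identity	accession
HALZIN_54	48442	49500	352	+	RND family efflux transporter, MFP subunit	Idiomarina sediminum	Gammaproteobacteria	44%	WP_026860724
HALZIN_399	433553	434005	150	+	MerR family Cd(II)/Pb(II)-responsive transcriptional regulator	Halomonas lutea	Gammaproteobacteria	75%	WP_019019418
HALZIN_733	778272	780812	846	+	Heavy metal translocating P-type ATPase ZntA	Gracilimonas tropica	Sphingobacteriia	59%	WP_020403952
HALZIN_916	977118	976882	78	-	Mercuric transport protein MerE	Burkholderia cepacia	Betaproteobacteria	99%	YP_006965885
HALZIN_917	977480	977115	121	-	Transcriptional regulator MerD	Pseudomonas putida	Gammaproteobacteria	98%	WP_012806008
HALZIN_918	978239	977592	215	-	Alkylmercury lyase MerB	Paraglaciecola polaris	Gammaproteobacteria	84%	WP_007106069
HALZIN_919	979028	978390	212	-	Alkylmercury lyase MerB	Paraglaciecola polaris	Gammaproteobacteria	94%	WP_007106069
HALZIN_920	979808	979179	209	-	Alkylmercury lyase MerB	Paraglaciecola polaris	Gammaproteobacteria	90%	WP_007106069
HALZIN_922	980118	980540	140	+	Transcriptional regulator MerR	Stenotrophomonas maltophilia	Gammaproteobacteria	99%	WP_005413398
HALZIN_934	994405	993521	294	-	Magnesium and cobalt efflux protein CorC	Chromohalobacter salexigens	Gammaproteobacteria	81%	WP_011507633
HALZIN_1240	1334217	1331998	739	-	Heavy metal translocating P-type ATPase	Halomonas sp.	Gammaproteobacteria	97%	WP_023004666
HALZIN_1392	1499237	1498659	192	-	Superoxide dismutase	Halomonas smyrnensis	Gammaproteobacteria	85%	WP_016854901
HALZIN_1411	1521826	1522995	389	+	RND family efflux transporter, MFP subunit	Halomonas lutea	Gammaproteobacteria	76%	WP_019017686
HALZIN_1413	1526330	1526785	151	+	Zinc uptake regulation protein ZUR	Halomonas lutea	Gammaproteobacteria	82%	WP_019017691
HALZIN_2047	2179598	2182789	1063	+	RND family efflux transporter protein	Pseudoxanthomonas suwonensis	Gammaproteobacteria	85%	WP_013535339
HALZIN_2196	2338252	2335574	892	-	Heavy metal translocating P-type ATPase ZntA	Halomonas lutea	Gammaproteobacteria	65%	WP_019020337
HALZIN_2208	2355137	2351976	1053	-	RND family efflux transporter protein	Pseudomonas alcaligenes	Gammaproteobacteria	58%	WP_021217164
HALZIN_2209	2356423	2351976	428	-	RND family efflux transporter, MFP subunit	Halomonas lutea	Gammaproteobacteria	53%	WP_019020155
HALZIN_2260	2411989	2410787	400	-	Multicopper oxidase	Sphingopyxis baekryungensis	Alphaproteobacteria	55%	WP_022673021
HALZIN_2261	2412630	2413034	134	+	Transcriptional regulator MerR	Halomonas lutea	Gammaproteobacteria	90%	WP_019017365
HALZIN_2262	2413107	2415596	829	+	Heavy metal translocating P-type ATPase	Halomonas lutea	Gammaproteobacteria	92%	WP_019017357
HALZIN_2264	2416527	2416976	149	+	Transcriptional regulator MerR	Halomonas lutea	Gammaproteobacteria	89%	WP_026300314
HALZIN_2268	2423176	2423622	148	+	CopG family transcriptional regulator	Halomonas lutea	Gammaproteobacteria	80%	WP_019017364
HALZIN_2271	2424931	2425086	51	+	Copper resistance protein CopC	Hyphomonas neptunium	Alphaproteobacteria	51%	WP_011646711
HALZIN_2272	2425115	2425978	287	+	Copper resistance protein CopD	Thialkalivibrio sp.	Gammaproteobacteria	43%	WP_018881395
HALZIN_2469	2658088	2657690	132	-	Transcriptional regulator MerR	Halomonas lutea	Gammaproteobacteria	90%	WP_019020805
HALZIN_2470	2658244	2658588	114	+	Mercuric transport protein MerT	Halomonas lutea	Gammaproteobacteria	78%	WP_019020806
HALZIN_2471	2658620	2658925	101	+	Periplasmic mercury(+2) binding protein MerP	Halomonas lutea	Gammaproteobacteria	82%	WP_019020807
HALZIN_2472	2658988	2660622	544	+	Mercuric reductase, MerA family	Halomonas lutea	Gammaproteobacteria	93%	WP_019020808
HALZIN_2675	2872087	2872584	165	+	Transcriptional regulator MerR	Halomonas sp.	Gammaproteobacteria	66%	WP_023005510
HALZIN_3265	3489632	3489021	203	-	Superoxide dismutase	Halomonas lutea	Gammaproteobacteria	74%	WP_019019731
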