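species_no,species,iv_s1,b_s1,grp_s1,iv_s2,b_s2,grp_s2,iv_s3,b_s3,grp_s3,comment
1,Kobresia humilis,—,—,—,0.07,1.00,N/A,—,—,—,
2,Dracocephalum heterophyllum,0.01,1.00,b,0.05,1.23,b,0.01,1.80,b,
3,Artemisia sacrorum,0.01,1.80,N/A,—,—,—,—,—,—,
4,Agropyron cristatum,0.19,2.51,N/A,—,—,—,0.05,1.00,N/A,
5,Descurainia sophia,—,—,—,0.29,1.00,N/A,—,—,—,
6,Plantago asiatica,0.01,1.60,a,0.15,1.24,a,0.04,1.00,a,
7,Elymus nutans,0.09,2.00,N/A,0.48,3.09,N/A,0.10,5.05,N/A,
8,Potentilla conferta,0.05,3.94,a,0.09,1.97,a,0.11,3.36,a,
9,Astragalus bhotanensis,0.06,1.00,b,0.01,1.47,b,0.01,1.00,b,
10,Potentilla multifida,—,—,—,0.04,1.00,N/A,0.02,1.42,N/A,
11,Astragalus polycladus,—,—,—,0.08,1.00,N/A,0.05,2.32,N/A,
12,Carex kansuensis,0.40,4.58,c,0.24,3.76,c,0.21,5.33,c,
13,Triglochin maritimum,—,—,—,0.07,1.02,N/A,—,—,—,
14,Glaux maritima,0.28,1.18,N/A,0.15,3.74,N/A,0.05,1.61,N/A,
15,Carex atrofusca subsp. minor,0.35,2.72,e,0.24,2.75,e,0.03,1.00,e,
16,Gentiana pseudoaquatica,—,—,—,0.01,1.00,N/A,—,—,—,S2 cell printed as 0.01/100; width read as 1.00 (presumed typo)
17,Potentilla anserina,0.24,3.90,a,0.18,3.50,a,0.23,5.57,a,
18,Leymus secalinus,0.40,2.71,b,0.45,4.14,b,0.71,5.60,b,
19,Oxytropis coerulea,—,—,—,—,—,—,0.02,1.00,N/A,
20,Artemisia frigida,0.04,2.48,N/A,—,—,—,0.13,2.27,N/A,
21,Oxytropis falcata,—,—,—,0.03,1.72,N/A,0.03,1.00,N/A,
22,Gentiana squarrosa,0.04,2.22,a,0.09,2.12,a,0.05,1.05,a,
23,Iris lactea var. chinensis,—,—,—,0.08,1.00,N/A,0.51,2.95,N/A,
24,Silene conoidea,0.03,1.53,N/A,0.03,1.00,N/A,—,—,—,
25,Ranunculus membranaceus,0.06,2.90,a,0.08,1.95,a,0.11,3.12,a,
26,Thermopsis lanceolata,0.26,3.76,b,0.37,2.22,b,0.13,2.95,b,
27,Taraxacum mongolicum,0.13,2.22,a,0.09,3.07,a,0.15,2.97,a,
28,Koeleria cristata,—,—,—,—,—,—,0.05,1.73,N/A,
29,Rubia cordifolia,—,—,—,—,—,—,0.08,1.47,N/A,
30,Lancea tibetica,—,—,—,0.09,1.06,N/A,0.01,2.37,N/A,
31,Mulgedium tataricum,—,—,—,—,—,—,0.01,1.00,N/A,
32,Artemisia desertorum,0.08,2.11,b,0.04,1.00,b,0.02,1.00,b,
33,Saussurea arenaria,—,—,—,—,—,—,0.08,1.28,N/A,
34,Anemone obtusiloba subsp. ovalifolia,—,—,—,0.03,1.53,N/A,—,—,—,
35,Triglochin palustre,0.07,4.92,d,0.04,1.00,d,0.06,2.92,d,
36,Potentilla chinensis,—,—,—,—,—,—,0.01,1.00,N/A,
37,Polygonum sibiricum,0.09,2.74,c,0.01,1.00,c,0.02,1.18,c,
38,Kobresia tibetica,0.68,4.86,d,0.64,6.57,d,0.67,5.97,d,
39,Primula forbesii,—,—,—,0.03,2.51,N/A,0.05,1.00,N/A,
40,Chenopodium ficifolium,—,—,—,0.03,1.38,N/A,—,—,—,
41,Kalidium foliatum,0.03,1.00,e,0.03,2.80,e,0.01,1.00,e,
42,Silene galliea,0.06,2.39,a,0.07,2.21,a,0.06,3.40,a,
43,Poa annua,0.31,2.82,N/A,0.19,4.64,N/A,0.17,3.59,N/A,
44,Rumex crispus,—,—,—,0.03,1.80,N/A,—,—,—,
45,Artemisia scoparia,0.07,1.35,b,0.03,1.00,b,0.01,1.00,b,
46,Aster tataricus,0.01,1.00,N/A,0.04,1.15,N/A,—,—,—,
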