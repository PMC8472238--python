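metabolite	logFC	aveExpr	p	adjP
L-Proline	0.910	19.269	1.02e-06	0.00014
L-Glutamic acid	1.406	19.899	2.04e-06	0.00018
N-Acetylglutamic acid	1.146	13.495	7.33e-07	0.00014
Adenosine monophosphate	0.925	20.923	3.23e-06	0.00018
Adenosine diphosphate	0.925	20.923	3.23e-06	0.00018
L-Threonine	1.281	18.628	9.24e-06	0.00036
L-Leucine	0.870	17.672	1.18e-05	0.00036
D-Glucose 6-phosphate	2.226	12.018	1.23e-05	0.00036
Citric acid	0.872	18.512	1.38e-05	0.00036
Inositol 1-phosphate	0.959	13.174	1.45e-05	0.00036
(S)-Methyl-3-hydroxybutanoate	0.935	16.364	1.51e-05	0.00036
Putrescine	1.179	14.878	2.05e-05	0.00044
D-Fructose 1,6-bisphosphate	2.035	12.807	2.18e-05	0.00044
D-Fructose	1.167	15.985	2.89e-05	0.00055
L-Valine	0.787	18.180	3.55e-05	0.00060
L-Isoleucine	0.794	16.510	3.63e-05	0.00060
L-Homocysteine	-2.332	19.231	3.89e-05	0.00061
Inosine 5prime-monophosphate	1.158	15.513	4.43e-05	0.00066
D-Glucose	1.418	14.891	5.85e-05	0.00080
Urea	1.599	18.093	6.27e-05	0.00080
L-Glutamyl-L-glutamine	-1.885	27.116	6.07e-05	0.00080
5prime-Deoxy-5prime-(methylthio)adenosine	0.732	12.146	6.81e-05	0.00080
(5Z,8Z,11Z,14Z)-Icosatetra-5,8,11,14-enoic acid	1.032	12.834	6.63e-05	0.00080
L-Rhamnose	0.805	15.911	7.07e-05	0.00080
S-Adenosyl methionine	-0.994	23.740	9.39e-05	0.00102
L-Threonic acid	0.685	16.744	0.00010	0.00106
Xanthine	-0.590	24.310	0.00011	0.00112
Glycerol	0.743	19.067	0.00013	0.00123
Uracil	-0.903	21.188	0.00013	0.00123
L-Serine	0.580	20.901	0.00014	0.00128
L-Phenylalanine	1.143	16.688	0.00014	0.00128
Riboflavin	-1.161	20.071	0.00018	0.00157
Erythritol	0.696	13.022	0.00021	0.00178
Orthophosphate	0.612	20.971	0.00029	0.00232
L-Dehydroascorbic acid	0.691	21.847	0.00032	0.00252
alpha-Ketoglutaric acid	1.783	12.766	0.00033	0.00252
Succinic acid	0.743	17.429	0.00034	0.00252
L-Methionine	0.909	16.361	0.00041	0.00296
1-Methyl-4-Imidazoleacetic acid	-0.837	21.803	0.00044	0.00312
Dopamine	-1.285	21.788	0.00046	0.00312
Choline	-0.431	26.902	0.00051	0.00333
L-Malic acid	0.695	17.421	0.00060	0.00389
alpha-D-Glucose 1-phosphate	0.608	16.334	0.00065	0.00409
Acetylcholine	-0.927	23.071	0.00067	0.00415
Guanidineacetic acid	0.821	20.099	0.00080	0.00480
Cholesterol	1.261	19.067	0.00081	0.00480
gamma-Glutamyl-tyrosine	-1.785	19.524	0.00084	0.00487
L-Phenylalanyl-L-glutamic acid	0.898	18.323	0.00089	0.00497
L-Tryptophan	1.611	14.883	0.00090	0.00497
Sucrose	6.158	13.392	0.00101	0.00541
3-Methoxytyramine	-1.329	19.231	0.00106	0.00555
Hydroxymethylphosphonic acid	-0.787	23.679	0.00115	0.00590
Cysteinylglycine	-4.028	21.772	0.00118	0.00598
L-Cystine	0.874	11.928	0.00123	0.00601
L-Lysine	-0.351	24.204	0.00123	0.00601
Xylitol	0.809	14.890	0.00140	0.00671
L-Valylglycine	0.679	18.356	0.00151	0.00707
myo-Inositol 2-phosphate	0.595	12.668	0.00152	0.00707
Quinic acid	0.856	11.418	0.00157	0.00714
Pantothenic acid	0.685	13.364	0.00159	0.00714
gamma-Glutamyl-leucine	-0.625	20.675	0.00168	0.00745
L-Homoserine	0.690	13.175	0.00201	0.00876
L-Tryptophyl-L-glutamic acid	1.067	17.063	0.00243	0.01042
O-Acetyl-L-homoserine	-0.758	25.057	0.00256	0.01082
2-Hydroxypyridine	0.676	18.513	0.00267	0.01111
L-Tyrosylglycine	0.669	17.228	0.00276	0.01131
Cytidine	-0.498	24.940	0.00283	0.01144
3-Ureidopropanoic acid	-0.797	16.984	0.00307	0.01222
L-Tyrosyl-L-glutamine	0.694	16.728	0.00317	0.01246
Pyroglutamic acid	0.419	23.178	0.00351	0.01361
sn-Glycerol 3-phosphate	0.544	19.750	0.00409	0.01542
L-Alanine	0.468	21.447	0.00456	0.01700
Thiaminpyrophosphate	0.972	17.802	0.00465	0.01708
L-Tyrosine	1.005	18.152	0.00495	0.01796
Serotonin	-0.856	19.538	0.00630	0.02227
5-Hydroxy-D,L-lysine	-0.541	16.762	0.00655	0.02274
L-Argininosuccinic acid	0.489	20.133	0.00659	0.02274
Uric acid	-0.872	20.411	0.00739	0.02490
L-Prolyl-L-threonine	0.456	17.391	0.00754	0.02491
Caffeic acid	0.846	11.955	0.00757	0.02491
L-Glutamine	0.415	23.021	0.00793	0.02579
gamma-Glutamyl-tryptophan	-1.178	18.306	0.00813	0.02614
S-(2-Carboxyethyl)cysteine	-0.912	19.479	0.00890	0.02799
Cytidine monophosphate	0.449	24.217	0.00890	0.02799
Uridine	-0.650	23.353	0.00964	0.02996
L-Valyl-L-alanine	1.011	18.636	0.01030	0.03168
Spermidine	-0.449	22.564	0.01043	0.03174
Spermine	-1.144	20.609	0.01090	0.03252
Pyruvic acid	0.570	16.746	0.01126	0.03319
(3-Carboxypropyl) trimethylammonium	-0.226	25.234	0.01211	0.03533
Urocanic acid	1.357	20.985	0.01319	0.03809
Glyceraldehyde 3-phosphate	1.960	19.691	0.01448	0.04138
Rutin	1.789	11.194	0.01504	0.04256
Guanosine	-0.551	26.262	0.01548	0.04336
Stearic acid (FA 18:0)	0.412	17.346	0.01606	0.04447
L-Lysyl-L-glutamic acid	-0.465	17.413	0.01619	0.04447
Xanthosine	-0.864	18.294	0.01649	0.04486
Palmitic acid (FA 16:0)	0.457	17.561	0.01711	0.04611
Cytidine 5prime-diphosphoethanolamine	-0.249	23.064	0.01821	0.04817
L-Phenylalanyl-L-threonine	0.550	16.795	0.01842	0.04826
1-Methylnicotinamide	-0.390	19.488	0.01907	0.04951
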