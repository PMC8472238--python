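pathway	n_features	n_down	n_up	direction	p	adjP	group
Starch and sucrose metabolism	3	0	3	Up	1.00e-06	1.02e-05	Carbohydrate metabolism
Glyoxylate and dicarboxylate metabolism	11	0	8	Up	8.00e-06	6.97e-05	Carbohydrate metabolism
Galactose metabolism	4	0	4	Up	1.20e-05	7.86e-05	Carbohydrate metabolism
Fructose and mannose metabolism	3	0	3	Up	1.40e-05	7.91e-05	Carbohydrate metabolism
Glycolysis/Gluconeogenesis	5	0	5	Up	5.40e-05	0.000199	Carbohydrate metabolism
Citrate cycle (TCA cycle)	7	0	7	Up	9.60e-05	0.000301	Carbohydrate metabolism
Pentose phosphate pathway	3	0	3	Up	0.000106	0.000309	Carbohydrate metabolism
Butanoate metabolism	6	0	6	Up	0.000115	0.000313	Carbohydrate metabolism
Ascorbate and aldarate metabolism	3	0	3	Up	0.00013	0.000332	Carbohydrate metabolism
Pentose and glucuronate interconversions	5	0	5	Up	0.000211	0.000508	Carbohydrate metabolism
Pyruvate metabolism	6	0	6	Up	0.000333	0.000717	Carbohydrate metabolism
Propanoate metabolism	4	0	3	Up	0.000623	0.001215	Carbohydrate metabolism
Oxidative phosphorylation	5	0	4	Up	0.000295	0.000671	Energy metabolism
Sulfur metabolism	6	2	4	Up	0.025918	0.034278	Energy metabolism
Biosynthesis of unsaturated fatty acids	4	0	3	Up	0.001717	0.002815	Lipid metabolism
Primary bile acid biosynthesis	3	0	2	Up	0.00549	0.008336	Lipid metabolism
Glycerophospholipid metabolism	4	2	1	Down	0.01947	0.027526	Lipid metabolism
Pyrimidine metabolism	16	7	3	Down	0.116182	0.136098	Nucleotide metabolism
Purine metabolism	20	7	5	Up	0.257673	0.270886	Nucleotide metabolism
Arginine biosynthesis	10	0	8	Up	1.00e-06	1.02e-05	Amino acid metabolism
Valine, leucine, and isoleucine degradation	3	0	3	Up	9.00e-06	6.97e-05	Amino acid metabolism
Alanine, aspartate, and glutamate metabolism	12	0	10	Up	1.80e-05	8.97e-05	Amino acid metabolism
Valine, leucine, and isoleucine biosynthesis	4	0	4	Up	2.50e-05	0.0001	Amino acid metabolism
Phenylalanine metabolism	5	0	5	Up	6.20e-05	0.00021	Amino acid metabolism
Arginine and proline metabolism	17	3	9	Up	0.000503	0.00103	Amino acid metabolism
Cysteine and methionine metabolism	13	4	9	Up	0.001386	0.00247	Amino acid metabolism
Phenylalanine, tyrosine, and tryptophan biosynthesis	3	0	3	Up	0.00163	0.002784	Amino acid metabolism
Glycine, serine, and threonine metabolism	13	4	7	Up	0.00343	0.005408	Amino acid metabolism
Lysine degradation	7	5	1	Down	0.07318	0.093761	Amino acid metabolism
Histidine metabolism	9	2	3	Up	0.143679	0.163634	Amino acid metabolism
Tyrosine metabolism	7	2	4	Up	0.214087	0.230988	Amino acid metabolism
Tryptophan metabolism	4	1	2	Up	0.377303	0.386735	Amino acid metabolism
D-Glutamine and D-glutamate metabolism	3	0	3	Up	2.00e-06	2.05e-05	Metabolism of other amino acids
Taurine and hypotaurine metabolism	7	1	5	Up	0.001137	0.002118	Metabolism of other amino acids
beta-Alanine metabolism	9	4	2	Down	0.113484	0.136098	Metabolism of other amino acids
Glutathione metabolism	9	4	4	Up	0.184715	0.204683	Metabolism of other amino acids
Porphyrin and chlorophyll metabolism	3	0	2	Up	2.30e-05	0.0001	Metabolism of cofactors and vitamins
Nicotinate and nicotinamide metabolism	8	1	5	Up	0.00984	0.014408	Metabolism of cofactors and vitamins
Thiamine metabolism	8	3	4	Up	0.022741	0.031079	Metabolism of cofactors and vitamins
Vitamin B6 metabolism	3	0	1	Up	0.110406	0.136098	Metabolism of cofactors and vitamins
Pantothenate and CoA biosynthesis	8	3	3	Up	0.505619	0.505619	Metabolism of cofactors and vitamins
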