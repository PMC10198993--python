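chembl_id,target_name,gene_symbol
CHEMBL256,Adenosine A3 receptor,ADORA3
CHEMBL3577,Aldehyde dehydrogenase 1A1,ALDH1A1
CHEMBL1795085,Ataxin-2,ATXN2
CHEMBL5393,ATP-binding cassette sub-family G member 2,ABCG2
CHEMBL1741193,Chromobox protein homolog 1,CBX1
CHEMBL2231,Cytochrome P450 1A1,CYP1A1
CHEMBL3356,Cytochrome P450 1A2,CYP1A2
CHEMBL4878,Cytochrome P450 1B1,CYP1B1
CHEMBL3622,Cytochrome P450 2C19,CYP2C19
CHEMBL289,Cytochrome P450 2D6,CYP2D6
CHEMBL340,Cytochrome P450 3A4,CYP3A4
CHEMBL5542,DNA polymerase eta,POLH
CHEMBL5619,DNA-(apurinic or apyrimidinic site) lyase,APEX1
CHEMBL1293278,Geminin,GMNN
CHEMBL1293226,Lysine-specific demethylase 4D-like,KDM4E
CHEMBL4040,MAP kinase ERK2,MAPK1
CHEMBL2093861,Menin/Histone-lysine N-methyltransferase MLL,MEN1
CHEMBL2288,Peptidyl-prolyl cis-trans isomerase NIMA-interacting 1,PIN1
CHEMBL1795091,Regulator of G-protein signaling 4,RGS4
CHEMBL2147,Serine/threonine-protein kinase PIM1,PIM1
CHEMBL3797,Serine-protein kinase ATM,ATM
CHEMBL2362981,TAR DNA-binding protein 43,TARDBP
CHEMBL2034804,Taste receptor type 2-member 31,TAS2R31
CHEMBL1075138,Tyrosyl-DNA phosphodiesterase 1,TDP1
CHEMBL1977,Vitamin D receptor,VDR
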