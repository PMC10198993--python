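mirna,site_start,site_end,logit_prob,dg_hybrid,evidence
hsa-miR-193b-3p,308,336,0.773477,-23.6,false
hsa-miR-4311,671,685,0.891580,-17.7,false
hsa-miR-27a-5p,680,699,0.781724,-19.1,true
hsa-miR-5680,819,839,0.858980,-18,false
hsa-miR-26a-5p,926,938,0.738008,-17.4,true
hsa-miR-26b-5p,926,938,0.738008,-17.4,true
hsa-miR-1297,928,938,0.695976,-15.1,false
hsa-miR-1287-5p,1847,1869,0.701477,-19.9,false
hsa-miR-215-5p,3116,3135,0.710925,-21.2,false
hsa-miR-181a-5p,3504,3531,0.849549,-16.9,true
hsa-miR-181c-5p,3504,3531,0.834222,-14.6,false
hsa-miR-181b-5p,3505,3531,0.863551,-20.5,true
hsa-miR-181d-5p,3505,3531,0.853119,-18.6,false
hsa-miR-4262,3516,3531,0.851064,-15.2,false
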