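chimpanzee,group,n_observations,acquired,observation_time_h,rate_of_observation,n_solves,trained
BJ,1,205,0,71.38,2.87,0,0
Bob,1,13,0,71.38,0.18,0,0
Booboo,1,0,0,71.38,0,0,0
Brenda,1,56,0,71.38,0.78,0,0
Chrissy,1,21,1,28.99,0.72,333,0
Genny,1,24,0,71.38,0.34,0,0
Gerard,1,0,0,71.38,0,0,0
Girly,1,0,0,71.38,0,0,0
Gonzaga,1,99,0,71.38,1.39,0,0
Ilse,1,32,0,71.38,0.45,0,0
Ingrid,1,13,0,71.38,0.18,0,0
Innocentia,1,44,0,71.38,0.62,0,0
Irene,1,153,0,71.38,2.14,0,0
Pal,1,1,0,71.38,0.01,0,0
Rachel,1,9,1,2.32,3.88,926,0
Regina,1,166,1,45.77,3.63,1048,0
Renate,1,406,0,71.38,5.69,0,0
Rita,1,NA,NA,NA,NA,1970,1
Rusty,1,252,1,49.17,5.12,1,0
Tara,1,3,0,71.38,0.04,0,0
Tobar,1,7,0,71.38,0.1,0,0
Carol,2,17,0,71.38,0.24,0,0
Charity,2,209,1,69.38,3.01,23,0
Claire,2,0,0,71.38,0,0,0
Coco,2,3,0,71.38,0.04,0,0
Daisey,2,75,0,71.38,1.05,0,0
Danny,2,43,1,71.38,9.85,3,0
David,2,0,0,71.38,0,0,0
Debbie,2,13,0,71.38,0.18,0,0
Diana,2,93,1,36.11,2.58,377,0
Dizzy,2,188,0,71.38,2.63,0,0
Dolly,2,19,1,29.2,0.65,1381,0
Donna,2,25,0,71.38,0.35,0,0
Dora,2,33,0,71.38,0.46,0,0
Doug,2,0,0,71.38,0,0,0
Jacky,2,239,0,71.38,3.35,0,0
Jane,2,19,0,71.38,0.27,0,0
John,2,174,0,71.38,2.44,0,0
Jones,2,274,0,71.38,3.84,0,0
Judy,2,135,0,71.38,1.89,0,0
LittleJenkins,2,49,1,50.4,0.97,232,0
Maggie,2,289,0,71.38,4.05,0,0
Martin,2,123,1,54.63,1.85,1,0
Mary,2,59,0,71.38,0.83,0,0
Masya,2,13,0,71.38,0.18,0,0
Max,2,124,0,71.38,1.74,0,0
Maxine,2,31,0,71.38,0.43,0,0
May,2,301,1,69.38,4.47,3,0
Mikey,2,41,0,71.38,0.57,0,0
Misha,2,43,0,71.38,0.6,0,0
Moyo,2,39,0,71.38,0.55,0,0
Nikkie,2,32,1,49.15,0.65,213,0
Nina,2,8,0,71.38,0.11,0,0
Noel,2,14,0,71.38,0.2,0,0
Pan,2,0,0,71.38,0,0,0
Pippa,2,NA,NA,NA,NA,3453,1
Tess,2,14,1,54.78,0.33,179,0
Tilly,2,16,1,38.35,0.42,159,0
Trixie,2,11,0,71.38,0.15,0,0
Violet,2,38,0,71.38,0.53,0,0
Vis,2,25,0,71.38,0.35,0,0
Zsabu,2,9,0,71.38,0.13,0,0
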