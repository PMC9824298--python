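name,chrom,pos,maf,na,ne,shannon_i,ho,pic,pi
1_SNP_1,1,20555681,0.493,2.000,2.000,0.693,0.487,0.375,0.375
2_SNP_1,1,203492932,0.468,2.000,1.991,0.691,0.556,0.375,0.375
3_SNP_1,1,42572356,0.458,2.000,1.991,0.691,0.299,0.374,0.376
1_SNP_2,2,79515402,0.489,2.000,2.000,0.693,0.470,0.375,0.375
2_SNP_2,2,38822259,0.486,2.000,1.993,0.691,0.393,0.374,0.376
3_SNP_2,2,68696654,0.458,2.000,1.979,0.688,0.504,0.372,0.378
1_SNP_3,3,21564028,0.482,2.000,1.998,0.693,0.470,0.375,0.375
2_SNP_3,3,160712162,0.475,2.000,1.976,0.687,0.427,0.375,0.375
3_SNP_3,3,134058046,0.472,2.000,1.995,0.692,0.538,0.374,0.376
1_SNP_4,4,96565277,0.500,2.000,1.999,0.693,0.487,0.375,0.375
2_SNP_4,4,14898710,0.493,2.000,1.999,0.693,0.402,0.375,0.375
3_SNP_4,4,170831355,0.461,2.000,1.954,0.681,0.350,0.369,0.381
1_SNP_5,5,3073649,0.486,2.000,1.999,0.693,0.453,0.375,0.375
2_SNP_5,5,12398569,0.458,2.000,1.932,0.675,0.487,0.371,0.379
3_SNP_5,5,56402023,0.458,2.000,1.995,0.692,0.487,0.374,0.376
1_SNP_6,6,178268444,0.475,2.000,1.996,0.692,0.462,0.372,0.378
2_SNP_6,6,28314239,0.472,2.000,1.998,0.693,0.402,0.375,0.375
3_SNP_6,6,78265333,0.468,2.000,1.954,0.681,0.470,0.369,0.381
1_SNP_7,7,175065396,0.482,2.000,1.985,0.689,0.436,0.373,0.377
2_SNP_7,7,28988576,0.454,2.000,1.993,0.691,0.444,0.371,0.379
3_SNP_7,7,47570898,0.447,2.000,1.954,0.681,0.436,0.369,0.381
1_SNP_8,8,42937619,0.489,2.000,1.993,0.691,0.393,0.374,0.376
2_SNP_8,8,117013679,0.486,2.000,1.993,0.691,0.444,0.374,0.376
3_SNP_8,8,43579005,0.479,2.000,1.993,0.691,0.530,0.374,0.376
1_SNP_9,9,97146833,0.496,2.000,1.999,0.693,0.436,0.375,0.375
2_SNP_9,9,14194449,0.486,2.000,1.999,0.693,0.479,0.375,0.375
3_SNP_9,9,33065116,0.486,2.000,1.995,0.692,0.470,0.374,0.376
1_SNP_10,10,120082494,0.493,2.000,1.999,0.693,0.427,0.375,0.375
2_SNP_10,10,162024357,0.486,2.000,1.998,0.693,0.521,0.375,0.375
3_SNP_10,10,14142424,0.482,2.000,1.996,0.692,0.479,0.375,0.375
1_SNP_11,11,103843763,0.496,2.000,1.995,0.692,0.590,0.374,0.376
2_SNP_11,11,120074865,0.482,2.000,1.985,0.689,0.590,0.373,0.377
3_SNP_11,11,115906813,0.454,2.000,1.995,0.692,0.453,0.374,0.376
1_SNP_12,12,157283886,0.465,2.000,1.999,0.693,0.419,0.374,0.376
2_SNP_12,12,84717331,0.447,2.000,1.998,0.693,0.402,0.374,0.376
3_SNP_12,12,119752353,0.466,2.000,1.993,0.691,0.444,0.374,0.376
1_SNP_13,13,110373506,0.461,2.000,1.972,0.686,0.521,0.375,0.375
2_SNP_13,13,68674252,0.458,2.000,1.972,0.686,0.453,0.366,0.384
3_SNP_13,13,103578624,0.447,2.000,1.963,0.684,0.453,0.370,0.380
1_SNP_14,14,33020570,0.486,2.000,1.998,0.693,0.556,0.375,0.375
2_SNP_14,14,52333124,0.482,2.000,1.999,0.693,0.453,0.375,0.375
3_SNP_14,14,102052966,0.472,2.000,2.000,0.693,0.462,0.375,0.375
1_SNP_15,15,85702925,0.482,2.000,1.995,0.692,0.436,0.374,0.376
2_SNP_15,15,108863635,0.482,2.000,1.998,0.693,0.538,0.375,0.375
3_SNP_15,15,102549019,0.472,2.000,1.999,0.693,0.470,0.375,0.375
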