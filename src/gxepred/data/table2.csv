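team,avg_rmse,avg_rmse_rank,avg_pearson,avg_pearson_rank,global_rmse,global_rmse_rank,global_pearson,global_pearson_rank
CLAC,2.329,1,0.357,1,2.458,1,0.631,2
igorkf,2.345,2,,,2.464,2,0.600,6
phenomaize,2.374,3,0.238,8,2.470,3,0.617,4
UCD_MegaLMM,2.387,4,0.338,3,2.505,6,0.616,5
CGM,2.391,5,0.353,2,2.490,5,0.587,7
Purdue,2.402,6,0.161,15,2.488,4,0.631,3
SmAL,2.425,7,0.146,17,2.525,7,0.586,8
ML_APT,2.472,8,0.191,13,2.600,8,0.564,10
MPB_Group,2.544,9,0.255,6,2.741,11,0.494,13
AIBreeding,2.544,10,0.220,9,2.758,14,0.439,15
AgroStat,2.562,11,0.100,20,2.646,9,0.554,11
arulrich,2.575,12,0.205,12,2.726,10,0.510,12
DataJanitors,2.587,13,0.256,5,2.752,12,0.644,1
CropsAreCool,2.616,14,0.161,14,2.805,15,0.413,19
AllModelsAreWrong,2.646,15,0.272,4,2.754,13,0.575,9
agAdaptAR,2.685,16,0.151,16,2.848,18,0.400,22
CropEnthusiast,2.710,17,0.116,19,2.844,17,0.437,16
DeepCropVision,2.739,18,-0.131,29,2.829,16,0.388,23
supermanwasd,2.746,19,0.243,7,2.915,21,0.409,21
BioSense,2.747,20,0.131,18,2.892,19,0.410,20
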