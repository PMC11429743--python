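team,rank,classical_ml,linear_mixed_blup,deep_learning,other_strategy,ensemble
CLAC,1,1,1,0,0,1
igorkf,2,1,0,0,0,0
phenomaize,3,0,1,0,0,0
UCD_MegaLMM,4,0,1,0,0,0
CGM,5,0,1,0,0,0
Purdue,6,1,1,0,0,1
SmAL,7,0,0,1,1,0
ML_APT,8,1,1,0,0,1
MPB_Group,9,0,1,1,0,0
AIBreeding,10,1,1,1,0,1
AgroStat,11,1,0,0,0,1
arulrich,12,1,0,0,0,0
DataJanitors,13,1,1,0,0,1
CropsAreCool,14,1,0,0,0,1
AllModelsAreWrong,15,1,1,0,0,1
agAdaptAR,16,1,0,1,0,1
DeepCropVision,18,0,0,1,0,1
supermanwasd,19,0,0,0,0,1
BioSense,20,1,0,0,1,0
Kernel of Truth,21,1,1,0,0,1
AIMaize,24,1,1,1,0,1
EnBiSys,25,0,0,1,0,0
Genetwister,26,0,1,0,0,0
gartybois,27,1,1,0,0,0
Niche Squad,28,0,0,1,0,0
uwaBioinfo,29,1,0,0,0,1
TinyAfrica,30,1,0,1,0,0
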