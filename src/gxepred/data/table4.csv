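team,rank,genetics,weather,soil,environment_covariates,field_management,experimental_design,other_factors
CLAC,1,1,1,1,1,1,0,0
igorkf,2,0,1,1,1,1,0,0
phenomaize,3,1,0,0,0,0,1,0
UCD_MegaLMM,4,1,0,0,0,0,1,0
CGM,5,1,0,0,0,0,0,1
Purdue,6,1,1,1,0,0,1,0
SmAL,7,1,1,1,1,1,0,0
ML_APT,8,1,1,1,1,1,1,0
MPB_Group,9,1,1,1,0,1,0,1
AIBreeding,10,1,1,1,1,0,0,0
AgroStat,11,1,1,0,0,0,0,0
arulrich,12,1,1,1,0,0,0,0
DataJanitors,13,1,0,0,1,1,1,0
CropsAreCool,14,0,1,1,1,1,1,0
AllModelsAreWrong,15,1,1,1,1,0,0,1
agAdaptAR,16,1,1,1,1,0,0,1
DeepCropVision,18,1,1,1,1,1,0,1
supermanwasd,19,1,1,1,1,0,0,0
BioSense,20,1,1,1,1,1,0,0
Kernel of Truth,21,1,0,0,0,1,0,0
AIMaize,24,1,1,1,1,0,0,0
EnBiSys,25,1,1,1,1,1,0,0
Genetwister,26,1,0,0,0,0,1,0
gartybois,27,1,1,1,1,1,1,0
Niche Squad,28,1,0,1,1,0,0,0
uwaBioinfo,29,1,1,1,0,0,0,0
TinyAfrica,30,1,1,1,1,1,0,1
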