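model_id,part,term_kind,var1,var2,coefficient,scale
OLS1,main,intercept,,,0.13583,identity
OLS1,main,linear,TOTAL,,0.00693,identity
OLS2,main,intercept,,,0.02434,identity
OLS2,main,linear,PWB,,0.02103,identity
OLS2,main,linear,SWB,,0.00118,identity
OLS2,main,linear,EWB,,0.00368,identity
OLS2,main,linear,FWB,,0.00386,identity
OLS2,main,linear,BCS,,0.00722,identity
OLS3,main,intercept,,,0.03209,identity
OLS3,main,linear,PWB,,0.02101,identity
OLS3,main,linear,EWB,,0.00400,identity
OLS3,main,linear,FWB,,0.00433,identity
OLS3,main,linear,BCS,,0.00728,identity
OLS4,main,intercept,,,-0.73772,identity
OLS4,main,linear,PWB,,0.05172,identity
OLS4,main,linear,EWB,,0.02837,identity
OLS4,main,linear,FWB,,0.01108,identity
OLS4,main,linear,BCS,,0.03138,identity
OLS4,main,squared,PWB,,-0.00088,identity
OLS4,main,squared,EWB,,-0.00076,identity
OLS4,main,squared,FWB,,-0.00017,identity
OLS4,main,squared,BCS,,-0.00045,identity
OLS5,main,intercept,,,-0.9110,identity
OLS5,main,linear,PWB,,0.05918,identity
OLS5,main,linear,EWB,,0.01932,identity
OLS5,main,linear,FWB,,0.02086,identity
OLS5,main,linear,BCS,,0.03505,identity
OLS5,main,squared,PWB,,-0.00030,identity
OLS5,main,squared,EWB,,-0.00029,identity
OLS5,main,squared,FWB,,0.00006,identity
OLS5,main,squared,BCS,,0.00011,identity
OLS5,main,interaction,PWB,EWB,0.00006,identity
OLS5,main,interaction,PWB,FWB,-0.00019,identity
OLS5,main,interaction,PWB,BCS,-0.00111,identity
OLS5,main,interaction,EWB,FWB,-0.00019,identity
OLS5,main,interaction,EWB,BCS,-0.00019,identity
OLS5,main,interaction,FWB,BCS,-0.00036,identity
TOBIT4,main,intercept,,,-0.60177,identity
TOBIT4,main,linear,PWB,,0.04438,identity
TOBIT4,main,linear,EWB,,0.02293,identity
TOBIT4,main,linear,FWB,,0.00821,identity
TOBIT4,main,linear,BCS,,0.02609,identity
TOBIT4,main,squared,PWB,,-0.00062,identity
TOBIT4,main,squared,EWB,,-0.00057,identity
TOBIT4,main,squared,FWB,,-0.00003,identity
TOBIT4,main,squared,BCS,,-0.00032,identity
TOBIT5,main,intercept,,,-0.77881,identity
TOBIT5,main,linear,PWB,,0.05329,identity
TOBIT5,main,linear,EWB,,0.01407,identity
TOBIT5,main,linear,FWB,,0.01547,identity
TOBIT5,main,linear,BCS,,0.03107,identity
TOBIT5,main,squared,PWB,,-0.00007,identity
TOBIT5,main,squared,EWB,,-0.00023,identity
TOBIT5,main,squared,FWB,,0.00013,identity
TOBIT5,main,squared,BCS,,0.00018,identity
TOBIT5,main,interaction,PWB,EWB,0.00001,identity
TOBIT5,main,interaction,PWB,FWB,-0.00013,identity
TOBIT5,main,interaction,PWB,BCS,-0.00114,identity
TOBIT5,main,interaction,EWB,FWB,-0.00010,identity
TOBIT5,main,interaction,EWB,BCS,-0.00005,identity
TOBIT5,main,interaction,FWB,BCS,-0.00032,identity
TPM4,part1,intercept,,,0.00048,odds_ratio
TPM4,part1,linear,PWB,,0.62518,odds_ratio
TPM4,part1,linear,FWB,,0.90802,odds_ratio
TPM4,part1,linear,BCS,,1.55562,odds_ratio
TPM4,part1,squared,PWB,,1.01569,odds_ratio
TPM4,part1,squared,FWB,,1.00524,odds_ratio
TPM4,part1,squared,BCS,,0.99500,odds_ratio
TPM4,part2,intercept,,,-0.81605,identity
TPM4,part2,linear,PWB,,0.05972,identity
TPM4,part2,linear,FWB,,0.02163,identity
TPM4,part2,linear,BCS,,0.04312,identity
TPM4,part2,squared,PWB,,-0.00106,identity
TPM4,part2,squared,FWB,,-0.00048,identity
TPM4,part2,squared,BCS,,-0.00069,identity
TPM5,part1,intercept,,,4.89e-06,odds_ratio
TPM5,part1,linear,PWB,,0.76743,odds_ratio
TPM5,part1,linear,FWB,,0.89512,odds_ratio
TPM5,part1,linear,BCS,,1.78533,odds_ratio
TPM5,part1,squared,PWB,,1.01664,odds_ratio
TPM5,part1,squared,FWB,,1.00599,odds_ratio
TPM5,part1,squared,BCS,,0.99905,odds_ratio
TPM5,part1,interaction,PWB,FWB,1.00542,odds_ratio
TPM5,part1,interaction,PWB,BCS,0.98847,odds_ratio
TPM5,part1,interaction,FWB,BCS,0.99508,odds_ratio
TPM5,part2,intercept,,,-1.02358,identity
TPM5,part2,linear,PWB,,0.06598,identity
TPM5,part2,linear,FWB,,0.03590,identity
TPM5,part2,linear,BCS,,0.04396,identity
TPM5,part2,squared,PWB,,-0.00033,identity
TPM5,part2,squared,FWB,,-0.00019,identity
TPM5,part2,squared,BCS,,-0.00015,identity
TPM5,part2,interaction,PWB,FWB,-0.00059,identity
TPM5,part2,interaction,PWB,BCS,-0.00105,identity
TPM5,part2,interaction,FWB,BCS,-0.00042,identity
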