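id,site,arch,sex,wear_stage,cft,ci,cc,dsr,n_accentuated,footnote_a,footnote_b
CA T.17 LL,Casalmoro,lower,M,1,418,199,219,3.05,3,1,0
CA T.17 UR,Casalmoro,upper,,1,367,174,193,3.18,1,0,0
CA T.19 UL,Casalmoro,upper,M,1,353,171,182,3.16,1,1,0
CA T.19 LL,Casalmoro,lower,,1,401,175,226,3.25,2,0,0
CA T.20 UL,Casalmoro,upper,M,3,386,176,210,3.18,1,0,0
CA T.24 LR,Casalmoro,lower,M,4,404,149,255,3.10,2,0,0
CA T.36 UL,Casalmoro,upper,M,1,358,165,193,3.23,1,1,0
CA T.37 UR,Casalmoro,upper,M,2,369,198,171,3.24,0,0,0
CA T.44 UL,Casalmoro,upper,M,3,374,180,194,3.23,0,0,0
CA T.55 LL,Casalmoro,lower,F,1,401,175,226,3.10,0,1,0
CA T.59a LR,Casalmoro,lower,F,2,390,182,208,3.19,1,0,0
CA T.59a UL,Casalmoro,upper,,3,369,181,188,3.27,0,0,0
CA T.59b UL,Casalmoro,upper,F,3,343,166,177,3.17,0,1,0
GUID T.6 LR,Guidizzolo,lower,F,1,418,185,233,3.15,0,0,0
GUID T.8 LR,Guidizzolo,lower,M,4,392,135,257,3.12,1,1,0
GUID T.14 LR,Guidizzolo,lower,M,2,418,175,243,3.08,0,1,0
GUID T.20 UR,Guidizzolo,upper,M,2,356,181,175,3.21,0,0,0
GUID T.31 LR,Guidizzolo,lower,F,3,389,165,224,3.11,4,1,0
GUID T.33 UR,Guidizzolo,upper,F,3,307,195,112,3.19,0,0,1
GUID T.39 LR,Guidizzolo,lower,M,1,410,179,231,3.24,1,1,0
GUID T.43 LR,Guidizzolo,lower,M,2,383,150,233,3.21,0,1,0
GUID T.43 UR,Guidizzolo,upper,,3,359,160,199,3.18,0,0,0
GUID T.48 LR,Guidizzolo,lower,F,2,388,169,219,3.24,0,0,0
GUID T.49 LR,Guidizzolo,lower,M,2,411,187,224,3.18,3,1,0
GUID T.49 UL,Guidizzolo,upper,,3,357,201,156,3.11,0,1,0
GUID T.49b LL,Guidizzolo,lower,M,2,408,178,230,3.14,3,0,0
GUID T.52 LL,Guidizzolo,lower,M,2,378,185,193,3.13,1,0,0
GUID T.54 UL,Guidizzolo,upper,M,2,n.a.,185,n.a.,3.23,0,0,1
GUID T.61 LR,Guidizzolo,lower,F,5,398,88,310,3.07,6,0,0
GUID T.65 LR,Guidizzolo,lower,M,2,383,172,211,3.17,1,0,0
GUID T.65 UR,Guidizzolo,upper,,3,344,187,157,3.15,2,0,0
GUID T.67 LL,Guidizzolo,lower,M,3,383,164,219,3.19,0,0,0
GUID T.67 UL,Guidizzolo,upper,,3,325,172,153,3.18,0,0,0
GUID T.89 UL,Guidizzolo,upper,M,3,350,195,155,3.14,4,0,0
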