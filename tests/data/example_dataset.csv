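ID,TIME,EVID,AMT,DUR,DV,MDV,KIND,WT,HT,SCR,AGE,PRETERM,SEX,ALT,AST,BUN,CYSC,ALB,TP,COMED,EGFR,GROUP
S0001,0,1,90.27137821,1,,1,,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,8,1,90.27137821,1,,1,,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,16,1,90.27137821,1,,1,,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,24,1,90.27137821,1,,1,,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,31.5,0,,,2.433007466,0,trough,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,32,1,90.27137821,1,,1,,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,33.5,0,,,9.13310501,0,peak,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0001,40,1,90.27137821,1,,1,,6.770353365,62.17315778,14.32867787,1,0,M,35.29647314,36.37569452,2.54187674,1.410523533,22.20732098,78.79106069,1,172.608264,augmented
S0002,0,1,53.80517377,1,,1,,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,8,1,53.80517377,1,,1,,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,16,1,53.80517377,1,,1,,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,24,1,53.80517377,1,,1,,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,31.5,0,,,7.897617382,0,trough,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,32,1,53.80517377,1,,1,,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,33.5,0,,,15.07602628,0,peak,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0002,40,1,53.80517377,1,,1,,4.035388033,52.87316273,9.674669826,2,1,F,38.45827218,63.52087376,3.926158454,1.718138836,33.59602521,80.9409911,1,159.428273,augmented
S0003,0,1,102.6515016,1,,1,,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,8,1,102.6515016,1,,1,,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,16,1,102.6515016,1,,1,,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,24,1,102.6515016,1,,1,,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,31.5,0,,,8.028570956,0,trough,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,32,1,102.6515016,1,,1,,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,33.5,0,,,17.75966632,0,peak,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
S0003,40,1,102.6515016,1,,1,,7.698862622,56.24609296,15.31514258,4,0,F,31.51650581,51.77170733,4.74987256,1.845606358,32.16068368,68.55168481,1,146.09525,augmented
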