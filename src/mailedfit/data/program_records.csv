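system_id,program_year,clinic_count,adaptations,kits_mailed,screened_count,fit_type,prior_crc_study
S1,2016,2,M;I;E,354,69,OC,0
S1,2017,2,M;Ph;S;E,194,68,OC,0
S2,2017,5,M;Ph;S,630,198,OC,1
S3,2016,2,M;Ph;S,111,25,OC,0
S3,2017,2,M;Ph;S,116,35,OC,0
S4,2016,4,M;Ph,756,108,OC,0
S4,2017,4,M;Ph;S;E,379,104,OC,0
S5,2016,5,S;I,326,86,OC,1
S5,2017,5,S;I,417,111,OC,1
S6,2017,1,M;Ph,189,49,OC,0
S7,2016,8,M;S;I,329,93,OC,0
S7,2017,8,M;S;I,354,87,OC,0
S8,2016,7,I,628,124,OC,1
S8,2017,7,Ph;S;I,479,117,OC,1
S9,2016,4,M;Ph,757,154,OC,0
S9,2017,4,M;Ph,626,152,OC,0
S10,2016,1,M,132,20,OC,0
S10,2017,1,M;Ph;S,94,17,OC,0
S11,2016,1,M,103,4,OC,0
S12,2016,1,M;Ph;S,293,66,OC,0
S13,2017,1,M,105,20,OTHER,0
S14,2016,2,M;E,57,14,OTHER,0
S14,2017,2,M;E,70,13,OTHER,0
S15,2017,1,M;E,89,12,OTHER,0
S16,2016,5,M;Ph,369,53,OTHER,0
S16,2017,5,M;Ph;S,343,42,OTHER,0
S17,2016,1,M,44,4,OTHER,0
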