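algorithm,dose,mean,lcl,ucl
ASiR20,1,4.06,4.03,4.09
ASiR40,1,3.91,3.88,3.93
ASiR70,1,3.64,3.61,3.66
FBP,1,4.20,4.17,4.22
MBIR,1,2.68,2.65,2.70
ASiR20,1.5,3.82,3.80,3.85
ASiR40,1.5,3.67,3.64,3.70
ASiR70,1.5,3.40,3.38,3.43
FBP,1.5,3.96,3.94,3.99
MBIR,1.5,2.58,2.56,2.61
ASiR20,3,3.49,3.46,3.52
ASiR40,3,3.34,3.31,3.36
ASiR70,3,3.07,3.04,3.09
FBP,3,3.63,3.60,3.66
MBIR,3,2.46,2.43,2.48
ASiR20,6,3.17,3.14,3.19
ASiR40,6,3.01,2.98,3.04
ASiR70,6,2.74,2.72,2.77
FBP,6,3.30,3.28,3.33
MBIR,6,2.32,2.29,2.34
ASiR20,12,2.83,2.80,2.85
ASiR40,12,2.67,2.64,2.70
ASiR70,12,2.40,2.37,2.43
FBP,12,2.97,2.94,2.99
MBIR,12,2.20,2.18,2.23
ASiR20,18,2.58,2.55,2.61
ASiR40,18,2.43,2.40,2.45
ASiR70,18,2.16,2.13,2.18
FBP,18,2.72,2.69,2.74
MBIR,18,2.03,2.00,2.06
ASiR20,24,2.48,2.45,2.51
ASiR40,24,2.33,2.30,2.35
ASiR70,24,2.06,2.04,2.09
FBP,24,2.60,2.57,2.62
MBIR,24,1.97,1.95,2.00
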