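algorithm,dose,mean,lcl,ucl
ASiR20,1,0.19,0.10,0.27
ASiR40,1,0.22,0.14,0.30
ASiR70,1,0.29,0.21,0.37
FBP,1,0.16,0.08,0.24
MBIR,1,0.81,0.73,0.90
ASiR20,1.5,0.28,0.19,0.36
ASiR40,1.5,0.32,0.23,0.40
ASiR70,1.5,0.40,0.32,0.49
FBP,1.5,0.26,0.18,0.34
MBIR,1.5,0.74,0.66,0.82
ASiR20,3,0.32,0.23,0.40
ASiR40,3,0.37,0.28,0.45
ASiR70,3,0.48,0.40,0.56
FBP,3,0.28,0.19,0.36
MBIR,3,0.89,0.80,0.97
ASiR20,6,0.48,0.39,0.56
ASiR40,6,0.55,0.47,0.64
ASiR70,6,0.71,0.63,0.80
FBP,6,0.42,0.34,0.50
MBIR,6,1.07,0.99,1.16
ASiR20,12,0.70,0.61,0.78
ASiR40,12,0.81,0.73,0.89
ASiR70,12,1.06,0.98,1.14
FBP,12,0.61,0.53,0.69
MBIR,12,1.37,1.29,1.45
ASiR20,18,0.81,0.73,0.89
ASiR40,18,0.94,0.86,1.03
ASiR70,18,1.23,1.15,1.31
FBP,18,0.71,0.63,0.79
MBIR,18,1.52,1.44,1.60
ASiR20,24,0.90,0.82,0.98
ASiR40,24,1.05,0.97,1.14
ASiR70,24,1.38,1.30,1.46
FBP,24,0.79,0.71,0.87
MBIR,24,1.58,1.50,1.67
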