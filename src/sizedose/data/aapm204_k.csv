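phantom,deff_cm,k
body32,6,2.97
body32,7,2.86
body32,8,2.76
body32,9,2.66
body32,10,2.57
body32,11,2.47
body32,12,2.38
body32,13,2.30
body32,14,2.22
body32,15,2.14
body32,16,2.06
body32,17,1.98
body32,18,1.91
body32,19,1.84
body32,20,1.78
body32,21,1.71
body32,22,1.65
body32,23,1.59
body32,24,1.53
body32,25,1.48
body32,26,1.43
body32,27,1.37
body32,28,1.32
body32,29,1.28
body32,30,1.23
body32,31,1.19
body32,32,1.14
body32,33,1.10
body32,34,1.06
body32,35,1.02
body32,36,0.99
body32,37,0.95
body32,38,0.92
body32,39,0.88
body32,40,0.85
body32,41,0.82
body32,42,0.79
body32,43,0.76
body32,44,0.74
body32,45,0.71
body32,46,0.68
body32,47,0.66
body32,48,0.64
body32,49,0.61
body32,50,0.59
body32,51,0.57
body32,52,0.55
body32,53,0.53
body32,54,0.51
body32,55,0.49
head16,6,1.49
head16,7,1.43
head16,8,1.38
head16,9,1.32
head16,10,1.27
head16,11,1.22
head16,12,1.18
head16,13,1.13
head16,14,1.09
head16,15,1.05
head16,16,1.01
head16,17,0.97
head16,18,0.93
head16,19,0.90
head16,20,0.86
head16,21,0.83
head16,22,0.80
head16,23,0.77
head16,24,0.74
head16,25,0.71
head16,26,0.69
head16,27,0.66
head16,28,0.63
head16,29,0.61
head16,30,0.59
head16,31,0.56
head16,32,0.54
head16,33,0.52
head16,34,0.50
head16,35,0.48
head16,36,0.47
head16,37,0.45
head16,38,0.43
head16,39,0.41
head16,40,0.40
head16,41,0.38
head16,42,0.37
head16,43,0.35
head16,44,0.34
head16,45,0.33
head16,46,0.32
head16,47,0.30
head16,48,0.29
head16,49,0.28
head16,50,0.27
head16,51,0.26
head16,52,0.25
head16,53,0.24
head16,54,0.23
head16,55,0.22
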