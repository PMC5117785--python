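age_band,stage,n_stage,category,pct_cases,odds_ratio,lo,hi
25.5-34,1A,1780,not_screened,31.5,1,,
25.5-34,1A,1780,regular,35.7,0.76,0.65,0.88
25.5-34,1A,1780,irregular,32.8,0.95,0.80,1.12
25.5-34,1B,984,not_screened,40.2,1,,
25.5-34,1B,984,regular,31.7,0.59,0.48,0.71
25.5-34,1B,984,irregular,28.0,0.72,0.58,0.88
25.5-34,2,214,not_screened,54.7,1,,
25.5-34,2,214,regular,28.5,0.28,0.17,0.43
25.5-34,2,214,irregular,16.8,0.39,0.25,0.60
25.5-34,3plus,87,not_screened,56.3,1,,
25.5-34,3plus,87,regular,32.2,0.16,0.06,0.37
25.5-34,3plus,87,irregular,11.4,0.27,0.13,0.56
35-64,1A,1921,not_screened,19.3,1,,
35-64,1A,1921,regular,38.6,0.33,0.27,0.38
35-64,1A,1921,irregular,17.0,0.53,0.43,0.64
35-64,1A,1921,very_irregular,25.2,0.87,0.72,1.06
35-64,1B,2231,not_screened,23.6,1,,
35-64,1B,2231,regular,39.7,0.25,0.21,0.28
35-64,1B,2231,irregular,15.4,0.38,0.31,0.46
35-64,1B,2231,very_irregular,21.2,0.62,0.51,0.74
35-64,2,929,not_screened,43.9,1,,
35-64,2,929,regular,23.3,0.10,0.07,0.12
35-64,2,929,irregular,12.1,0.17,0.12,0.22
35-64,2,929,very_irregular,20.8,0.37,0.28,0.48
35-64,3plus,748,not_screened,57.6,1,,
35-64,3plus,748,regular,15.4,0.05,0.03,0.06
35-64,3plus,748,irregular,9.9,0.10,0.06,0.14
35-64,3plus,748,very_irregular,17.1,0.20,0.14,0.27
65-79,1A,66,not_screened,36.4,1,,
65-79,1A,66,regular,47.0,0.31,0.14,0.67
65-79,1A,66,irregular,6.1,0.30,0.08,1.04
65-79,1A,66,very_irregular,10.6,0.29,0.10,0.84
65-79,1B,306,not_screened,35.3,1,,
65-79,1B,306,regular,44.4,0.39,0.28,0.54
65-79,1B,306,irregular,8.5,0.53,0.31,0.91
65-79,1B,306,very_irregular,11.8,0.59,0.37,0.96
65-79,2,356,not_screened,39.3,1,,
65-79,2,356,regular,40.4,0.32,0.24,0.44
65-79,2,356,irregular,7.9,0.29,0.18,0.48
65-79,2,356,very_irregular,12.4,0.62,0.39,1.01
65-79,3plus,418,not_screened,47.6,1,,
65-79,3plus,418,regular,31.8,0.19,0.14,0.26
65-79,3plus,418,irregular,7.4,0.23,0.14,0.37
65-79,3plus,418,very_irregular,13.2,0.61,0.40,0.94
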