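diagnosis_band,death_band,observed_deaths,rr_no_screening,rr_no_screening_lo,rr_no_screening_hi,rr_all_regular,rr_all_regular_lo,rr_all_regular_hi,est_deaths_no_screening,est_deaths_all_regular
25-34,25-39,103,1.96,1.66,2.31,0.68,0.61,0.76,202,70
35-49,40-54,175,4.13,3.59,4.75,0.42,0.38,0.47,721,73
50-64,55-69,199,5.30,4.36,6.44,0.35,0.33,0.37,1054,70
65-79,70-84,216,2.51,2.18,2.90,0.61,0.58,0.65,542,132
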