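age_band,stage,fatality_pct
25.5-34,1A,1.4
25.5-34,1B,8.8
25.5-34,2,55.1
25.5-34,3plus,80.0
35-49,1A,1.4
35-49,1B,8.6
35-49,2,54.2
35-49,3plus,79.2
50-64,1A,2.5
50-64,1B,10.9
50-64,2,51.2
50-64,3plus,86.0
65-69,1A,2.1
65-69,1B,9.1
65-69,2,44.9
65-69,3plus,80.5
70-79,1A,1.5
70-79,1B,14.8
70-79,2,68.8
70-79,3plus,95.1
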