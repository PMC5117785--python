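quantity,value
total_cases,11619
staged_cases,10040
unknown_stage_cases,1579
observed_deaths_all_ages,796
observed_deaths_in_bands,692
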