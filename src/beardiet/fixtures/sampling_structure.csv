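species,sex,n_individuals,mass_min_kg,mass_max_kg,spring_days,summer_days,fall_days,total_days
grizzly,F,4,104,147,9,10,21,40
grizzly,M,6,102,215,10,7,13,30
black_sympatric,F,8,44,97,24,43,25,92
black_sympatric,M,9,80,149,18,21,13,52
black_allopatric,F,5,55,77,10,17,16,43
black_allopatric,M,5,64,116,7,7,3,17
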