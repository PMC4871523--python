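category,diet_type,n_bear_days,mean_samples_per_day,agveg_pct,bgveg_pct,cambium_pct,fruit_pct,nut_pct,insect_pct,vertebrate_pct
homogeneous,insect,45,3.9,4,0,0,13,0,82,1
homogeneous,agveg,40,4.7,86,0,0,0,0,13,1
homogeneous,fruit,30,4.4,4,1,0,78,1,16,0
homogeneous,vertebrate,26,5.5,8,0,0,2,0,5,85
homogeneous,nut,12,6.0,2,0,0,1,91,5,1
homogeneous,bgveg,7,5.2,10,79,0,2,1,5,3
mixed,insect-agveg,35,3.6,33,0,0,5,0,60,1
mixed,fruit-insect,20,5.7,8,1,0,43,1,40,8
mixed,agveg-vertebrate,18,5.5,53,0,0,0,1,13,32
mixed,insect-vertebrate,10,3.4,8,0,0,2,0,59,31
mixed,bgveg-mixed,9,4.6,10,47,0,6,0,14,22
mixed,agveg-fruit,8,3.8,41,0,0,51,0,5,3
mixed,cambium-mixed,7,2.8,54,0,10,0,0,27,9
mixed,nut-mixed,7,5.2,5,3,0,14,59,5,14
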