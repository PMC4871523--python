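food_type,scat_correction_factor,protein_kcal_per_g,carbohydrate_kcal_per_g,lipid_kcal_per_g,dry_energy_kcal_per_g,fresh_energy_kcal_per_g
agveg,0.3,3.47,4.07,8.37,2.43,0.98
bgveg,0.8,2.78,4.03,8.37,2.49,1.29
cambium,0.4,3.47,4.07,8.37,2.46,0.24
fruit,1.0,3.36,3.60,8.37,2.96,1.43
nut,1.5,3.47,4.07,8.37,3.35,3.15
fungi,1.0,2.62,4.07,8.37,2.96,0.31
insect,1.1,4.27,3.82,9.03,4.74,2.77
vert_small,1.5,4.27,3.82,9.03,4.61,1.27
vert_large,2.0,4.27,3.82,9.03,5.25,1.52
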