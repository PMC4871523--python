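taxon,food_type,basis,protein,carbohydrate,lipid,nondigestible,moisture,source
unidentified_agveg,agveg,dry,0.15,0.407469287469,0.03,0.412530712531,0.59670781893,synthetic type mean
unidentified_bgveg,bgveg,dry,0.08,0.521141439206,0.02,0.378858560794,0.481927710843,synthetic type mean
unidentified_cambium,cambium,dry,0.05,0.520663390663,0.02,0.409336609337,0.90243902439,synthetic type mean
unidentified_fruit,fruit,dry,0.05,0.682555555556,0.04,0.227444444444,0.516891891892,synthetic type mean
unidentified_nut,nut,dry,0.06,0.154987714988,0.3,0.485012285012,0.0597014925373,synthetic type mean
unidentified_fungi,fungi,dry,0.25,0.504643734644,0.03,0.215356265356,0.89527027027,synthetic type mean
unidentified_insect,insect,dry,0.55,0.20054973822,0.18,0.0694502617801,0.415611814346,synthetic type mean
unidentified_vert_small,vert_small,dry,0.65,0.0783769633508,0.17,0.101623036649,0.724511930586,synthetic type mean
unidentified_vert_large,vert_large,dry,0.6,0.041780104712,0.28,0.078219895288,0.710476190476,synthetic type mean
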