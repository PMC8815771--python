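dataset,SMOTE,B-SMOTE,SOMO,KmeansSMOTE,FSVM-CEN,FSVM-HYP,FSVM-WD,FSVM-BD,ACFSVM,DFSVM
Cargood,0.851,0.839,0.864,0.881,0.875,0.886,0.776,0.848,0.919,0.940
Cleveland0vs4,0.373,0.420,0.640,0.665,0.778,0.677,0.728,0.743,0.816,0.939
Ecoli0147vs2356,0.607,0.710,0.762,0.743,0.747,0.654,0.683,0.686,0.782,0.852
Ecoli01vs235,0.834,0.867,0.781,0.873,0.787,0.820,0.801,0.825,0.817,0.874
Ecoli0267vs35,0.807,0.771,0.825,0.855,0.765,0.822,0.848,0.836,0.869,0.922
Glass1,0.682,0.702,0.678,0.755,0.611,0.643,0.598,0.638,0.661,0.692
Glass6,0.901,0.884,0.861,0.878,0.862,0.910,0.892,0.891,0.904,0.939
Pageblocks0,0.890,0.903,0.852,0.903,0.908,0.898,0.874,0.916,0.917,0.915
Vehicle3,0.741,0.746,0.766,0.787,0.831,0.804,0.761,0.774,0.821,0.846
Yeast1vs7,0.418,0.435,0.509,0.555,0.611,0.668,0.627,0.662,0.659,0.697
Yeast3,0.837,0.831,0.851,0.863,0.905,0.896,0.891,0.910,0.901,0.917
Yeast6,0.625,0.703,0.593,0.655,0.849,0.593,0.813,0.801,0.805,0.856
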