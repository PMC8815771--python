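dataset,SMOTE,B-SMOTE,SOMO,KmeansSMOTE,FSVM-CEN,FSVM-HYP,FSVM-WD,FSVM-BD,ACFSVM,DFSVM
Cargood,0.716,0.693,0.649,0.758,0.616,0.662,0.586,0.687,0.774,0.834
Cleveland0vs4,0.349,0.393,0.553,0.549,0.574,0.541,0.615,0.662,0.819,0.824
Ecoli0147vs2356,0.469,0.622,0.676,0.647,0.597,0.591,0.463,0.531,0.533,0.716
Ecoli01vs235,0.674,0.739,0.690,0.741,0.601,0.711,0.634,0.576,0.654,0.809
Ecoli0267vs35,0.621,0.641,0.735,0.702,0.611,0.676,0.615,0.647,0.711,0.764
Glass1,0.634,0.606,0.612,0.689,0.583,0.588,0.575,0.584,0.636,0.629
Glass6,0.808,0.818,0.747,0.808,0.760,0.823,0.810,0.810,0.777,0.831
Pageblocks0,0.735,0.754,0.746,0.815,0.711,0.746,0.485,0.587,0.782,0.805
Vehicle3,0.631,0.634,0.676,0.694,0.712,0.699,0.622,0.638,0.725,0.737
Yeast1vs7,0.223,0.244,0.433,0.466,0.359,0.449,0.258,0.286,0.333,0.476
Yeast3,0.683,0.672,0.775,0.749,0.720,0.720,0.622,0.762,0.778,0.781
Yeast6,0.342,0.529,0.451,0.443,0.374,0.365,0.287,0.339,0.412,0.501
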