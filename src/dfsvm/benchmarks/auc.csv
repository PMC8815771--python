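dataset,SMOTE,B-SMOTE,SOMO,KmeansSMOTE,FSVM-CEN,FSVM-HYP,FSVM-WD,FSVM-BD,ACFSVM,DFSVM
Cargood,0.995,0.994,0.988,0.993,0.991,0.991,0.993,0.997,0.996,0.985
Cleveland0vs4,0.962,0.963,0.972,0.967,0.982,0.973,0.976,0.933,0.985,0.987
Ecoli0147vs2356,0.792,0.856,0.898,0.914,0.845,0.829,0.801,0.799,0.839,0.930
Ecoli01vs235,0.927,0.963,0.955,0.963,0.932,0.952,0.910,0.925,0.924,0.955
Ecoli0267vs35,0.937,0.915,0.929,0.949,0.906,0.922,0.939,0.939,0.923,0.988
Glass1,0.734,0.790,0.713,0.759,0.707,0.708,0.732,0.706,0.683,0.792
Glass6,0.974,0.983,0.969,0.967,0.971,0.982,0.978,0.983,0.950,0.989
Pageblocks0,0.960,0.963,0.959,0.971,0.960,0.975,0.962,0.970,0.961,0.960
Vehicle3,0.863,0.865,0.899,0.903,0.906,0.904,0.852,0.862,0.934,0.884
Yeast1vs7,0.697,0.717,0.745,0.748,0.817,0.816,0.740,0.776,0.763,0.819
Yeast3,0.933,0.932,0.970,0.964,0.964,0.959,0.957,0.974,0.945,0.968
Yeast6,0.880,0.911,0.857,0.726,0.921,0.905,0.915,0.922,0.917,0.935
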