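dataset,gmean_fsvm,gmean_svm,fmeasure_fsvm,fmeasure_svm,auc_fsvm,auc_svm
Ecoli0147vs2356,0.8260,0.8082,0.7060,0.6868,0.9284,0.9178
Ecoli01vs235,0.8687,0.8163,0.7628,0.5200,0.9334,0.9545
Ecoli0267vs35,0.9187,0.7986,0.7412,0.7270,0.9814,0.9698
Glass1,0.6971,0.6667,0.6134,0.5818,0.7699,0.7446
Yeast1vs7,0.6705,0.5029,0.4539,0.2630,0.7508,0.6655
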