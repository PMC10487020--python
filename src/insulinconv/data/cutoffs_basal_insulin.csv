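reference,assay_id,feeding,outcome,metric,cutoff
"Lindase et al., 2021",G,Fasted,EHC,Youden's index,9.5
"de Laat et al., 2022",G,Fasted,Cluster,Balanced sens. and spec.,10.4
"Olley et al., 2019",C,Fasted,CGIT,Youden's index,5.2
"Menzies-Gow et al., 2017",B,Unfasted,Laminitis,Youden's index,21.8
"Meier et al., 2018",A,Fasted,High NSC diet laminitis,CART,8.5
"Carter et al., 2009",B,Unfasted (hay),Pasture associated laminitis,AUC in ROC,32
EEG 2020,E,Unfasted (hay),,,31
EEG 2020,C,Unfasted (hay),,,20
"Köller et al., 2016",D,Unfasted (hay),Healthy,95% confidence interval,21
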