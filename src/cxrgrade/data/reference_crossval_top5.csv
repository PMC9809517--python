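architecture,balancing,segmentation,precision_mean,precision_sd,recall_mean,recall_sd,f1_mean,f1_sd,macro_mae_mean,macro_mae_sd,ma_hcs_mean
chexnet121,double,none,65.89,1.28,66.30,1.13,65.82,1.18,0.3944,0.0147,0.1481
chexnet121,under,none,65.36,1.26,65.47,1.15,65.06,1.32,0.3930,0.0126,0.1352
resnet50,under,none,64.88,1.10,64.81,0.82,64.33,0.85,0.4099,0.0147,0.1830
resnet50,double,spine,64.33,1.21,64.37,0.99,63.90,1.19,0.4149,0.0157,0.2057
vgg16,double,spine,62.02,1.31,61.18,1.27,61.44,1.27,0.4325,0.0182,0.1631
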