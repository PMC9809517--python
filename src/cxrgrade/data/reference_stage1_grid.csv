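architecture,balancing,segmentation,precision,recall,f1,macro_mae
chexnet121,under,none,65.18,64.90,64.41,0.3953
chexnet121,double,none,64.88,65.02,64.62,0.4023
resnet50,under,none,63.62,63.46,62.82,0.4097
resnet50,double,spine,63.85,64.24,63.91,0.4144
vgg16,double,spine,62.89,62.54,62.60,0.4151
vgg16,under,none,62.60,62.32,62.24,0.4161
chexnet121,double,spine,63.37,63.62,63.20,0.4193
vgg16,double,none,63.45,62.76,62.36,0.4210
chexnet121,under,spine,63.55,63.62,63.25,0.4214
resnet50,double,none,63.02,63.75,62.77,0.4238
resnet50,under,spine,63.79,62.72,62.60,0.4279
vgg16,over,lung,60.43,61.37,61.06,0.4320
vgg16,over,none,60.81,60.98,60.11,0.4371
chexnet121,over,none,61.56,61.76,60.85,0.4392
resnet50,double,lung,62.54,62.22,62.14,0.4412
vgg16,under,spine,62.32,62.43,61.56,0.4439
resnet50,under,lung,61.31,61.38,60.93,0.4454
chexnet121,over,spine,61.13,61.24,60.80,0.4489
resnet50,over,lung,59.63,60.58,59.64,0.4600
chexnet121,over,lung,58.94,59.23,58.39,0.4613
vgg16,under,lung,60.95,60.17,60.02,0.4612
vgg16,double,lung,61.01,61.07,60.73,0.4635
resnet50,over,spine,60.39,61.20,60.37,0.4665
chexnet121,under,lung,60.55,60.72,60.40,0.4669
resnet50,over,none,59.54,57.31,56.07,0.4864
chexnet121,double,lung,59.58,60.60,59.68,0.4973
vgg16,over,spine,35.79,46.46,38.04,0.9625
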