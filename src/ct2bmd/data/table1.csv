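contrast,correlation,energy,homogeneity,entropy,bmd
3,0.6936,0.5454,0.8889,2.7036,1.89847
3.3667,0.6639,0.3489,0.8722,3.9166,1.909341
5,0.6124,0.44,0.8333,3.5435,1.785716
5.05,0.5284,0.425,0.8083,3.2676,1.681617
5.25,0.5493,0.4514,0.8056,3.0029,1.686442
3.5,0.6576,0.5216,0.8704,2.7869,1.844213
5.5,0.4952,0.4883,0.8021,3.3537,1.897391
0.6,0.8589,0.4816,0.8817,2.7931,1.726328
6.6875,0.3527,0.2344,0.6302,3.3842,1.70792
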