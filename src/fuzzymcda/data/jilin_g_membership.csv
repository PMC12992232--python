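leaf,very unimportant,unimportant,average,important,very important
G1,0,0,0.294118,0.647059,0.058824
G2,0,0.058824,0.470588,0.352941,0.117647
G3,0,0.117647,0.352941,0.470588,0.058824
G4,0,0.117647,0.235294,0.647059,0
G5,0,0,0.588235,0.294118,0.117647
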