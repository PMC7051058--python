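gene
DPP10
HDAC9
TBXAS1
FBXL7
GSDMB
ORMDL3
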