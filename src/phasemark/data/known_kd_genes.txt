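# Known Kawasaki-disease genes from the laboratory literature, used as the
# reference feature set in the gene-set comparison.
# GPL6271 probe ID_REFs: TLR6 253/29567, COPB2 9368/34805, FCGR2A 12792,
# CD40 26186, BLK 33880/37136, CASP3 34697.
TLR6
COPB2
FCGR2A
CD40
BLK
CASP3
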