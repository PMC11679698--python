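element,mg_per_kg
Si,311400
Al,81500
Fe,35300
Ca,25660
K,23240
Mg,14960
Ti,3836
Mn,775
P,655
S,621
Ba,628
Cl,370
Sr,320
Zr,193
Rb,84
Cr,92
Zn,67
Cu,28
Pb,17
As,4.8
Br,1.6
Se,0.09
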