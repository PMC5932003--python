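# source: Rudnick & Gao (2003), upper continental crust, ppm (Al from 15.4 wt% Al2O3)
element,ppm
Al,81500
La,31
Ce,63
Pr,7.1
Nd,27
Sm,4.7
Eu,1.0
Gd,4.0
Tb,0.70
Dy,3.9
Ho,0.83
Er,2.3
Tm,0.30
Yb,2.0
Lu,0.31
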