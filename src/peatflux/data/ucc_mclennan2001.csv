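# source: McLennan (2001), upper continental crust, ppm (Al from 15.2 wt% Al2O3)
element,ppm
Al,80400
La,30
Ce,64
Pr,7.1
Nd,26
Sm,4.5
Eu,0.88
Gd,3.8
Tb,0.64
Dy,3.5
Ho,0.80
Er,2.3
Tm,0.33
Yb,2.2
Lu,0.32
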