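class,ocmin,ocmax,hcmin,hcmax,precedence
Lipid,0.0,0.3,1.5,2.5,1
Unsaturated hydrocarbon,0.0,0.125,0.8,1.5,2
Protein,0.3,0.55,1.5,2.3,3
Amino sugar,0.55,0.7,1.5,2.2,4
Carbohydrate,0.7,1.5,1.5,2.5,5
Lignin,0.125,0.65,0.8,1.5,6
Tannin,0.65,1.1,0.8,1.5,7
Condensed hydrocarbon,0.0,0.95,0.2,0.8,8
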