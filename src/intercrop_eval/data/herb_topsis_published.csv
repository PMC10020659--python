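treatment,d_plus,d_minus,closeness,rank
J-maize,0.051,0.085,0.625,2
J-rice,0.023,0.106,0.821,1
J-control,0.090,0.050,0.357,7
C-peanut,0.068,0.068,0.500,3
C-sesame,0.076,0.055,0.419,6
C-maize,0.076,0.075,0.496,4
C-mung bean,0.075,0.062,0.452,5
C-control,0.102,0.022,0.181,8
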