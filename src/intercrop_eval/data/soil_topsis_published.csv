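treatment,d_plus,d_minus,closeness,rank
J-maize,0.297,0.896,0.751,1
J-rice,0.581,0.721,0.554,2
J-control,0.889,0.403,0.312,7
C-peanut,0.618,0.535,0.464,4
C-sesame,0.603,0.597,0.497,3
C-maize,0.747,0.566,0.431,6
C-mung bean,0.719,0.611,0.460,5
C-control,0.889,0.239,0.212,8
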