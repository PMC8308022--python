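case,physical,social
1,35,52
2,35,40
3,65,0
4,30,4
5,50,12
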