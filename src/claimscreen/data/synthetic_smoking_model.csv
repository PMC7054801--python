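term,code_system,coefficient
constant,demographic,-0.3
1629,ICD9_DX,0.9
41401,ICD9_DX,0.25
49121,ICD9_DX,0.8
496,ICD9_DX,0.9
female,demographic,-0.5
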