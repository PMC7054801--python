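code,code_system,label
3051,ICD9_DX,tobacco use disorder
30510,ICD9_DX,"tobacco use disorder, unspecified"
30511,ICD9_DX,"tobacco use disorder, continuous"
30512,ICD9_DX,"tobacco use disorder, episodic"
30513,ICD9_DX,"tobacco use disorder, in remission"
V1582,ICD9_DX,history of tobacco use
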