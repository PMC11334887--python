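well,role,concentration,sample_id,replicate
A1,standard,0,,
A2,standard,5,,
A3,standard,10,,
A4,standard,15,,
A5,standard,20,,
B1,sample,,S1,1
B2,sample,,S1,2
B3,sample,,S1,3
C1,sample,,S2,1
C2,sample,,S2,2
C3,sample,,S2,3
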