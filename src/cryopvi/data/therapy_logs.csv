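patient_id,TZ,TI,TM,max_temperature,TT
1,10,23,32,-60,240
2,8,29,33,-42,240
3,12,36,42,-41,240
4,12,30,34,-63,240
5,13,31,35,-43,240
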