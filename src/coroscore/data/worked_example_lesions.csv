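patient_id,dominance,segment,stenosis_pct,composition
case01,right,Left main,30,mixed
case01,right,LAD proximal,30,mixed
case01,right,LAD mid,30,mixed
case01,right,1st diagonal,30,calcified
case01,right,LCx proximal,30,calcified
case01,right,RCA proximal,30,calcified
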