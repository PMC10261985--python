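study_id,arm,time_months,timepoint,stage,count
cusi,placebo,18,initial,0,20
cusi,placebo,18,initial,1,22
cusi,placebo,18,initial,2,4
cusi,placebo,18,initial,3,5
cusi,placebo,18,initial,4,0
cusi,placebo,18,final,0,18
cusi,placebo,18,final,1,16
cusi,placebo,18,final,2,3
cusi,placebo,18,final,3,5
cusi,placebo,18,final,4,0
cusi,pioglitazone,18,initial,0,15
cusi,pioglitazone,18,initial,1,22
cusi,pioglitazone,18,initial,2,6
cusi,pioglitazone,18,initial,3,7
cusi,pioglitazone,18,initial,4,0
cusi,pioglitazone,18,final,0,22
cusi,pioglitazone,18,final,1,13
cusi,pioglitazone,18,final,2,2
cusi,pioglitazone,18,final,3,3
cusi,pioglitazone,18,final,4,0
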