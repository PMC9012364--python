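# SYNTHETIC stand-in utility/disutility catalog: the published catalog was
# not available at cell level; values chosen once from BPH cost-utility
# literature ranges. See docs/methods.md.
item,kind,value
mild,utility_severity,0.95
moderate,utility_severity,0.9
severe,utility_severity,0.8
TUR syndrome,disutility_ae,0.15
Transfusion,disutility_ae,0.1
Immediate acute urinary retention,disutility_ae,0.1
Bladder spasm,disutility_ae,0.05
Urinary retention,disutility_ae,0.1
Urinary tract infection,disutility_ae,0.07
Pelvic pain,disutility_ae,0.07
Hematuria,disutility_ae,0.05
Dysuria,disutility_ae,0.05
Urinary urge incontinence,disutility_ae,0.08
Frequency and urgency,disutility_ae,0.05
Encrusted implant,disutility_ae,0.08
Urethral stricture,disutility_ae,0.1
Bladder neck contraction,disutility_ae,0.1
Erectile dysfunction,disutility_ae,0.12
Urinary incontinence,disutility_ae,0.11
TUR syndrome,recovery_time_ae,0.08
Transfusion,recovery_time_ae,0.05
Immediate acute urinary retention,recovery_time_ae,0.06
Bladder spasm,recovery_time_ae,0.1
Urinary retention,recovery_time_ae,0.12
Urinary tract infection,recovery_time_ae,0.08
Pelvic pain,recovery_time_ae,0.15
Hematuria,recovery_time_ae,0.08
Dysuria,recovery_time_ae,0.1
Urinary urge incontinence,recovery_time_ae,0.25
Frequency and urgency,recovery_time_ae,0.25
Encrusted implant,recovery_time_ae,0.25
Urethral stricture,recovery_time_ae,0.3
Bladder neck contraction,recovery_time_ae,0.3
Erectile dysfunction,recovery_time_ae,100.0
Urinary incontinence,recovery_time_ae,100.0
catheter,disutility_catheter,0.2
retreatment,disutility_retreatment,0.05
retreatment,retreatment_disutility_duration,0.25
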