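item,kind,value
office_visit,office_visit,87.0
medical_therapy,medical_therapy_annual,105.0
mild,followup_by_severity,87.0
moderate,followup_by_severity,97.0
severe,followup_by_severity,184.0
TUR syndrome,ae_unit,6554.0
Transfusion,ae_unit,6554.0
Immediate acute urinary retention,ae_unit,0.0
Bladder spasm,ae_unit,87.0
Urinary retention,ae_unit,174.0
Urinary tract infection,ae_unit,87.0
Pelvic pain,ae_unit,87.0
Hematuria,ae_unit,87.0
Dysuria,ae_unit,87.0
Urinary urge incontinence,ae_unit,87.0
Frequency and urgency,ae_unit,87.0
Encrusted implant,ae_unit,3285.0
Urethral stricture,ae_unit,3347.0
Bladder neck contraction,ae_unit,3179.0
Erectile dysfunction,ae_unit,0.0
Urinary incontinence,ae_unit,0.0
Erectile dysfunction,ae_annual,1370.0
Urinary incontinence,ae_annual,1354.0
PUL,retreatment,7258.0
WVTT,retreatment,1867.0
PVP,retreatment,4813.0
TURP,retreatment,5157.0
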