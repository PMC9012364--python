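name,is_surgical,procedure_cost,drug_cost_per_day,catheterization_rate,catheter_duration_days,extra_removal_visit_fraction,first_year_visits,retreat_schedule,retreat_mix
CT,False,0.0,3.73,0.0,0.0,0.5,2.0,0.0:0.009124116404740534;0.25:0.009124116404740534;0.5:0.009124116404740534;0.75:0.009124116404740534;1.0:0.036;2.0:0.036;3.0:0.036;4.0:0.036,WVTT:1.0
PUL,True,7258.0,0.0,0.514,1.0,0.5,2.0,0.0:0.020629638664440675;0.25:0.020629638664440675;0.5:0.020629638664440675;0.75:0.020629638664440675;1.0:0.08;2.0:0.08;3.0:0.08;4.0:0.08,medical_therapy:1.0
WVTT,True,1867.0,0.0,0.904,3.4,0.5,2.0,0.0:0.007585882718504244;0.25:0.007585882718504244;0.5:0.007585882718504244;0.75:0.007585882718504244;1.0:0.03;2.0:0.03;3.0:0.03;4.0:0.03,medical_therapy:1.0
PVP,True,4813.0,0.0,0.941,1.9,0.5,2.0,0.0:0.020097805527192203;0.25:0.020097805527192203;0.5:0.020097805527192203;0.75:0.020097805527192203;1.0:0.078;2.0:0.078;3.0:0.078;4.0:0.078,medical_therapy:1.0
TURP,True,5157.0,0.0,0.932,2.4,0.5,2.0,0.0:0.016136389926731276;0.25:0.016136389926731276;0.5:0.016136389926731276;0.75:0.016136389926731276;1.0:0.063;2.0:0.063;3.0:0.063;4.0:0.063,medical_therapy:1.0
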