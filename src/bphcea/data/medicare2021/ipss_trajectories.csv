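strategy,time_years,ipss_mean,ipss_sd
CT,0.0,22.0,4.8
CT,0.25,11.0,6.4
CT,0.5,10.5,6.2
CT,1.0,11.7,7.0
CT,2.0,11.6,6.5
CT,3.0,11.9,6.4
CT,4.0,12.8,7.7
CT,5.0,12.5,8.1
PUL,0.0,22.0,4.8
PUL,0.25,10.9,6.4
PUL,0.5,10.5,6.2
PUL,1.0,11.6,7.0
PUL,2.0,11.5,6.5
PUL,3.0,11.8,6.4
PUL,4.0,12.7,7.7
PUL,5.0,12.4,8.1
PVP,0.0,22.0,4.8
PVP,0.25,10.1,6.4
PVP,0.5,8.7,6.2
PVP,1.0,8.2,7.3
PVP,2.0,8.1,6.8
PVP,3.0,8.4,6.7
PVP,4.0,9.3,8.0
PVP,5.0,9.0,8.4
TURP,0.0,22.0,4.8
TURP,0.25,10.0,6.4
TURP,0.5,8.6,6.2
TURP,1.0,7.9,7.2
TURP,2.0,7.8,6.7
TURP,3.0,8.1,6.6
TURP,4.0,9.0,7.9
TURP,5.0,8.7,8.3
WVTT,0.0,22.0,4.8
WVTT,0.25,10.6,6.4
WVTT,0.5,9.8,6.2
WVTT,1.0,10.3,6.7
WVTT,2.0,10.2,6.2
WVTT,3.0,10.5,6.1
WVTT,4.0,11.4,7.4
WVTT,5.0,11.1,7.8
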