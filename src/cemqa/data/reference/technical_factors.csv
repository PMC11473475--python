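# Bundled transcription of the exposure technical factors and per-image MGD (mean and
# maximum half-dispersion over three repeated acquisitions) reported by a published
# three-vendor CEM phantom intercomparison (CIRS Model 022-style phantom, 55 mm, all
# available AEC modes). Values are as printed at source precision; 'flag' marks cells
# known to be inconsistent at printed precision (none here).
system,aec_mode,label,energy,anode,filter,kvp,mas_mean,mas_halfdisp,mgd_mean,mgd_halfdisp,flag
GE,AOP/STD,GE,LE,Rh,Ag,34,45.0,0.9,1.64,0.03,ok
GE,AOP/STD,GE,HE,Rh,Cu,49,111.3,0.4,0.70,0.00,ok
Hologic,AutoFilter,Hologic,LE,W,Ag,30,156.6,2.5,2.66,0.05,ok
Hologic,AutoFilter,Hologic,HE,W,Cu,49,97.6,2.0,0.84,0.02,ok
Siemens,dose level 125%,Siemens 125%,LE,W,Rh,29,215.0,0.6,2.39,0.02,ok
Siemens,dose level 125%,Siemens 125%,HE,W,Ti,49,46.8,0.0,0.75,0.00,ok
Siemens,dose level 112%,Siemens 112%,LE,W,Rh,29,191.0,1.6,2.12,0.02,ok
Siemens,dose level 112%,Siemens 112%,HE,W,Ti,49,42.3,0.2,0.68,0.00,ok
Siemens,dose level 100%,Siemens 100%,LE,W,Rh,29,172.4,1.5,1.91,0.02,ok
Siemens,dose level 100%,Siemens 100%,HE,W,Ti,49,42.3,0.2,0.61,0.00,ok
Siemens,dose level 89%,Siemens 89%,LE,W,Rh,29,154.2,0.0,1.70,0.01,ok
Siemens,dose level 89%,Siemens 89%,HE,W,Ti,49,34.4,0.0,0.56,0.00,ok
Siemens,dose level 80%,Siemens 80%,LE,W,Rh,29,138.6,1.2,1.54,0.01,ok
Siemens,dose level 80%,Siemens 80%,HE,W,Ti,49,31.7,0.2,0.51,0.00,ok
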