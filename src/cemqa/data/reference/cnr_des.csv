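# Bundled transcription of the mean CNR (and maximum half-dispersion over three repeats)
# measured on recombined DES images in the published three-vendor CEM phantom
# intercomparison, per phantom half and nominal iodine surface density (mg/cm^2).
# 'flag' = suspect marks cells transcribed verbatim that are inconsistent with the
# source's own printed ratio rows (apparent typographical errors); they are excluded
# from derived ratio summaries.
image_kind,half,iodine_mg_cm2,label,cnr_mean,cnr_halfdisp,flag
DES,adipose,2.0,GE,13.30,0.32,ok
DES,adipose,2.0,Hologic,9.90,0.66,ok
DES,adipose,2.0,Siemens 125%,7.01,0.12,ok
DES,adipose,2.0,Siemens 112%,6.57,0.09,ok
DES,adipose,2.0,Siemens 100%,6.04,0.16,ok
DES,adipose,2.0,Siemens 89%,5.96,0.10,ok
DES,adipose,2.0,Siemens 80%,5.74,0.18,ok
DES,adipose,1.0,GE,6.28,0.03,ok
DES,adipose,1.0,Hologic,4.54,0.17,ok
DES,adipose,1.0,Siemens 125%,3.80,0.17,ok
DES,adipose,1.0,Siemens 112%,3.61,0.15,ok
DES,adipose,1.0,Siemens 100%,3.55,0.20,ok
DES,adipose,1.0,Siemens 89%,1.53,0.07,suspect
DES,adipose,1.0,Siemens 80%,0.69,0.01,suspect
DES,adipose,0.5,GE,3.44,0.08,ok
DES,adipose,0.5,Hologic,2.92,0.06,ok
DES,adipose,0.5,Siemens 125%,1.63,0.07,ok
DES,adipose,0.5,Siemens 112%,1.54,0.04,ok
DES,adipose,0.5,Siemens 100%,1.53,0.07,ok
DES,adipose,0.5,Siemens 89%,1.49,0.04,ok
DES,adipose,0.5,Siemens 80%,1.45,0.05,ok
DES,adipose,0.2,GE,1.54,0.12,ok
DES,adipose,0.2,Hologic,1.54,0.07,ok
DES,adipose,0.2,Siemens 125%,0.82,0.06,ok
DES,adipose,0.2,Siemens 112%,0.75,0.14,ok
DES,adipose,0.2,Siemens 100%,0.69,0.01,ok
DES,adipose,0.2,Siemens 89%,0.64,0.10,ok
DES,adipose,0.2,Siemens 80%,0.64,0.12,ok
DES,glandular,2.0,GE,12.07,0.18,ok
DES,glandular,2.0,Hologic,9.58,0.30,ok
DES,glandular,2.0,Siemens 125%,6.61,0.10,ok
DES,glandular,2.0,Siemens 112%,6.30,0.17,ok
DES,glandular,2.0,Siemens 100%,6.15,0.04,ok
DES,glandular,2.0,Siemens 89%,5.70,0.15,ok
DES,glandular,2.0,Siemens 80%,5.53,0.02,ok
DES,glandular,1.0,GE,5.61,0.11,ok
DES,glandular,1.0,Hologic,4.88,0.14,ok
DES,glandular,1.0,Siemens 125%,3.61,0.09,ok
DES,glandular,1.0,Siemens 112%,3.44,0.10,ok
DES,glandular,1.0,Siemens 100%,3.35,0.18,ok
DES,glandular,1.0,Siemens 89%,3.07,0.10,ok
DES,glandular,1.0,Siemens 80%,2.90,0.10,ok
DES,glandular,0.5,GE,2.82,0.13,ok
DES,glandular,0.5,Hologic,3.12,0.04,ok
DES,glandular,0.5,Siemens 125%,1.55,0.02,ok
DES,glandular,0.5,Siemens 112%,1.49,0.06,ok
DES,glandular,0.5,Siemens 100%,1.41,0.08,ok
DES,glandular,0.5,Siemens 89%,1.45,0.04,ok
DES,glandular,0.5,Siemens 80%,1.28,0.04,ok
DES,glandular,0.2,GE,1.10,0.14,ok
DES,glandular,0.2,Hologic,1.56,0.03,ok
DES,glandular,0.2,Siemens 125%,0.70,0.04,ok
DES,glandular,0.2,Siemens 112%,0.66,0.08,ok
DES,glandular,0.2,Siemens 100%,0.67,0.05,ok
DES,glandular,0.2,Siemens 89%,0.58,0.08,ok
DES,glandular,0.2,Siemens 80%,0.64,0.04,ok
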