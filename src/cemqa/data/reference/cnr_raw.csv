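# Bundled transcription of the mean CNR (and maximum half-dispersion over three repeats)
# measured on DICOM For Processing LE/HE images in the published three-vendor CEM phantom
# intercomparison, per phantom half and nominal iodine surface density (mg/cm^2).
# 'flag' = suspect marks cells transcribed verbatim that are apparent typographical
# errors at source (out of family with the neighbouring AEC modes); they are excluded
# from derived ratio summaries.
image_kind,half,iodine_mg_cm2,label,cnr_mean,cnr_halfdisp,flag
LE,adipose,2.0,GE,4.84,0.10,ok
LE,adipose,2.0,Hologic,2.15,0.04,ok
LE,adipose,2.0,Siemens 125%,2.56,0.05,ok
LE,adipose,2.0,Siemens 112%,2.43,0.02,ok
LE,adipose,2.0,Siemens 100%,2.34,0.02,ok
LE,adipose,2.0,Siemens 89%,2.23,0.01,ok
LE,adipose,2.0,Siemens 80%,2.16,0.02,ok
LE,adipose,1.0,GE,2.63,0.10,ok
LE,adipose,1.0,Hologic,1.12,0.01,ok
LE,adipose,1.0,Siemens 125%,1.34,0.01,ok
LE,adipose,1.0,Siemens 112%,1.25,0.03,ok
LE,adipose,1.0,Siemens 100%,1.25,0.03,ok
LE,adipose,1.0,Siemens 89%,1.17,0.01,ok
LE,adipose,1.0,Siemens 80%,1.15,0.05,ok
LE,adipose,0.5,GE,1.25,0.03,ok
LE,adipose,0.5,Hologic,0.55,0.01,ok
LE,adipose,0.5,Siemens 125%,0.64,0.01,ok
LE,adipose,0.5,Siemens 112%,0.59,0.02,ok
LE,adipose,0.5,Siemens 100%,0.54,0.00,ok
LE,adipose,0.5,Siemens 89%,0.55,0.02,ok
LE,adipose,0.5,Siemens 80%,0.54,0.00,ok
LE,adipose,0.2,GE,0.56,0.06,ok
LE,adipose,0.2,Hologic,0.28,0.02,ok
LE,adipose,0.2,Siemens 125%,0.27,0.02,ok
LE,adipose,0.2,Siemens 112%,0.24,0.06,ok
LE,adipose,0.2,Siemens 100%,0.26,0.02,ok
LE,adipose,0.2,Siemens 89%,0.25,0.00,ok
LE,adipose,0.2,Siemens 80%,0.23,0.02,ok
LE,glandular,2.0,GE,3.47,0.03,ok
LE,glandular,2.0,Hologic,1.66,0.00,ok
LE,glandular,2.0,Siemens 125%,1.82,0.05,ok
LE,glandular,2.0,Siemens 112%,1.76,0.03,ok
LE,glandular,2.0,Siemens 100%,1.69,0.05,ok
LE,glandular,2.0,Siemens 89%,1.62,0.02,ok
LE,glandular,2.0,Siemens 80%,1.56,0.04,ok
LE,glandular,1.0,GE,1.91,0.02,ok
LE,glandular,1.0,Hologic,0.81,0.02,ok
LE,glandular,1.0,Siemens 125%,1.04,0.01,ok
LE,glandular,1.0,Siemens 112%,0.97,0.03,ok
LE,glandular,1.0,Siemens 100%,0.95,0.01,ok
LE,glandular,1.0,Siemens 89%,0.91,0.01,ok
LE,glandular,1.0,Siemens 80%,0.91,0.03,ok
LE,glandular,0.5,GE,1.09,0.03,ok
LE,glandular,0.5,Hologic,0.45,0.01,ok
LE,glandular,0.5,Siemens 125%,0.52,0.01,ok
LE,glandular,0.5,Siemens 112%,0.46,0.01,ok
LE,glandular,0.5,Siemens 100%,0.48,0.01,ok
LE,glandular,0.5,Siemens 89%,0.42,0.01,ok
LE,glandular,0.5,Siemens 80%,0.40,0.02,ok
LE,glandular,0.2,GE,0.55,0.03,ok
LE,glandular,0.2,Hologic,0.23,0.00,ok
LE,glandular,0.2,Siemens 125%,0.18,0.02,ok
LE,glandular,0.2,Siemens 112%,0.16,0.01,ok
LE,glandular,0.2,Siemens 100%,0.18,0.03,ok
LE,glandular,0.2,Siemens 89%,0.16,0.01,ok
LE,glandular,0.2,Siemens 80%,0.20,0.01,ok
HE,adipose,2.0,GE,9.51,0.24,ok
HE,adipose,2.0,Hologic,3.83,0.06,ok
HE,adipose,2.0,Siemens 125%,3.16,0.01,ok
HE,adipose,2.0,Siemens 112%,3.00,0.04,ok
HE,adipose,2.0,Siemens 100%,2.77,0.05,ok
HE,adipose,2.0,Siemens 89%,2.67,0.03,ok
HE,adipose,2.0,Siemens 80%,2.57,0.08,ok
HE,adipose,1.0,GE,4.80,0.06,ok
HE,adipose,1.0,Hologic,1.75,0.05,ok
HE,adipose,1.0,Siemens 125%,1.41,0.03,ok
HE,adipose,1.0,Siemens 112%,1.34,0.02,ok
HE,adipose,1.0,Siemens 100%,1.30,0.07,ok
HE,adipose,1.0,Siemens 89%,1.20,0.05,ok
HE,adipose,1.0,Siemens 80%,1.20,0.05,ok
HE,adipose,0.5,GE,2.72,0.05,ok
HE,adipose,0.5,Hologic,0.92,0.02,ok
HE,adipose,0.5,Siemens 125%,0.81,0.01,ok
HE,adipose,0.5,Siemens 112%,0.73,0.02,ok
HE,adipose,0.5,Siemens 100%,0.71,0.01,ok
HE,adipose,0.5,Siemens 89%,0.70,0.01,ok
HE,adipose,0.5,Siemens 80%,0.67,0.01,ok
HE,adipose,0.2,GE,1.25,0.06,ok
HE,adipose,0.2,Hologic,0.45,0.03,ok
HE,adipose,0.2,Siemens 125%,0.39,0.02,ok
HE,adipose,0.2,Siemens 112%,0.36,0.04,ok
HE,adipose,0.2,Siemens 100%,0.33,0.01,ok
HE,adipose,0.2,Siemens 89%,0.30,0.04,ok
HE,adipose,0.2,Siemens 80%,0.28,0.04,ok
HE,glandular,2.0,GE,8.72,0.19,ok
HE,glandular,2.0,Hologic,3.61,0.03,ok
HE,glandular,2.0,Siemens 125%,2.86,0.04,ok
HE,glandular,2.0,Siemens 112%,2.75,0.03,ok
HE,glandular,2.0,Siemens 100%,2.56,0.01,ok
HE,glandular,2.0,Siemens 89%,2.44,0.051,suspect
HE,glandular,2.0,Siemens 80%,2.33,0.01,ok
HE,glandular,1.0,GE,4.21,0.05,ok
HE,glandular,1.0,Hologic,1.68,0.01,ok
HE,glandular,1.0,Siemens 125%,1.40,0.02,ok
HE,glandular,1.0,Siemens 112%,1.36,0.03,ok
HE,glandular,1.0,Siemens 100%,1.28,0.04,ok
HE,glandular,1.0,Siemens 89%,0.22,0.02,suspect
HE,glandular,1.0,Siemens 80%,1.18,0.02,ok
HE,glandular,0.5,GE,2.63,0.05,ok
HE,glandular,0.5,Hologic,0.93,0.01,ok
HE,glandular,0.5,Siemens 125%,0.72,0.02,ok
HE,glandular,0.5,Siemens 112%,0.67,0.01,ok
HE,glandular,0.5,Siemens 100%,0.65,0.03,ok
HE,glandular,0.5,Siemens 89%,0.64,0.02,ok
HE,glandular,0.5,Siemens 80%,0.59,0.01,ok
HE,glandular,0.2,GE,1.16,0.08,ok
HE,glandular,0.2,Hologic,0.42,0.03,ok
HE,glandular,0.2,Siemens 125%,0.34,0.04,ok
HE,glandular,0.2,Siemens 112%,0.30,0.03,ok
HE,glandular,0.2,Siemens 100%,0.29,0.01,ok
HE,glandular,0.2,Siemens 89%,0.26,0.03,ok
HE,glandular,0.2,Siemens 80%,0.28,0.02,ok
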