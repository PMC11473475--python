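# Total-dose summary quantities as printed at source (mean +/- maximum half-dispersion,
# and percent increase over the GE reference). Empty cells were not printed at source.
# Used only to flag recomputed-from-rounded-Table-cells values that differ from the
# printed presentation (known rounding artifacts).
label,printed_total_mgy,printed_total_halfdisp,printed_increase_pct
GE,2.34,0.03,0.0
Hologic,3.50,0.05,49.6
Siemens 125%,3.14,0.01,
Siemens 112%,,,
Siemens 100%,2.53,0.02,8.0
Siemens 89%,,,-3.4
Siemens 80%,2.05,0.01,-12.4
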