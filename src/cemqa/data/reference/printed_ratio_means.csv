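# Mean CNR ratios (reference system GE over comparator) as printed at source, one
# decimal. Used to flag recomputed-from-rounded-cells values that differ from the
# printed presentation (known rounding artifacts), never to replace recomputation.
image_kind,comparator,printed_mean
LE,Hologic,2.3
LE,Siemens 125%,2.1
LE,Siemens 112%,2.3
LE,Siemens 100%,2.2
LE,Siemens 89%,2.4
LE,Siemens 80%,2.4
HE,Hologic,2.7
HE,Siemens 125%,3.3
HE,Siemens 112%,3.5
HE,Siemens 100%,3.7
HE,Siemens 89%,3.9
HE,Siemens 80%,4.0
DES,Hologic,1.1
DES,Siemens 125%,1.8
DES,Siemens 112%,1.9
DES,Siemens 100%,2.0
DES,Siemens 89%,2.1
DES,Siemens 80%,2.1
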