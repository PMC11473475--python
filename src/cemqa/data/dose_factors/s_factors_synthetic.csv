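# Synthetic representative s-factor table, version 1.0.
# s(anode, filter): spectrum correction per anode/filter combination, including the
# high-energy Cu/Ti beams used by CEM. NOT published values (chosen near the familiar
# order of magnitude); replace with a published transcription for absolute dosimetry.
anode,filter,s
Mo,Mo,1.0
Mo,Rh,1.017
Rh,Rh,1.06
Rh,Ag,1.042
W,Rh,1.042
W,Ag,1.042
Rh,Cu,1.28
W,Cu,1.28
W,Ti,1.25
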