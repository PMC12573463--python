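Treatment,Endpoint,Shape parameter,Scale parameter
Enza_ADT,rPFS,1.131400,0.007900
Enza_ADT,OS,1.426021,0.001476
Apa_ADT,rPFS,1.131400,0.006004
Apa_ADT,OS,1.426021,0.001461
Dar_ADT,rPFS,1.131400,0.006715
Dar_ADT,OS,1.426021,0.001830
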