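regimen,label,Enza_ADT,Apa_ADT,Dar_ADT
sl_docetaxel,Docetaxel + dexamethasone + ADT,8.4,26.8,22.7
sl_abiraterone,Abiraterone + methylprednisolone + ADT,4.5,14.5,12.8
sl_enzalutamide,Enzalutamide + ADT,42,6.5,3
sl_apalutamide,Apalutamide + ADT,0,0,1.5
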