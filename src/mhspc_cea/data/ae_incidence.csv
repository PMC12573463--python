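event,label,Enza_ADT,Apa_ADT,Dar_ADT
fatigue,Fatigue,1.7,0,0
hypertension,Hypertension,3.3,8.4,4.3
rash,Rash,0,6.3,0
fracture,Fracture,1,1.3,0
anemia,Anemia,0,0,3.1
back_pain,Back pain,0.9,2.3,1.1
ast,Elevated aspartate aminotransferase (AST),0,0,2.2
alt,Elevated alanine aminotransferase (ALT),0,0,2
neutropenia,Neutropenia,0.3,0,0
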