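group,n,auc,sen,spe
All participants,157,67.1,74.1,60.0
University hospital,151,66.9,74.0,59.8
Private practice (resident),6,71.3,76.7,65.8
Junior physicians,88,66.5,74.8,58.2
Attendings,15,66.4,72.7,60.0
Senior physicians,45,67.7,73.0,62.3
Chief physicians,3,71.3,73.3,69.2
Practical experience <= 2 years,46,66.2,76.0,56.5
Practical experience 2-4 years,37,66.4,73.8,59.1
Practical experience 4-12 years,32,67.9,73.3,62.5
Practical experience > 12 years,42,67.9,73.0,62.8
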