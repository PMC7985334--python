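patient_id,n_cps,hscl11_pre,oq30_pre,gad7_pre,phq9_pre,hscl11_s15,oq30_s15,gad7_s15,phq9_s15
A,15,2.09,2.03,9,15,1.91,2.17,8,16
B,0,2.36,2.27,16,18,2.09,1.87,22,21
C,12,2.70,2.17,14,17,2.36,1.97,16,21
D,18,2.77,2.40,15,13,2.73,1.83,15,16
E,19,2.50,1.93,12,17,1.91,2.20,10,14
F,21,3.05,2.17,14,14,,,,
G,20,1.34,1.14,8,5,1.45,1.17,6,8
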