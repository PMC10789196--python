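label	x_mm	y_mm	z_mm
Fp1	-24.9808732224	76.8832222609	26.2664445219
Fp2	24.9808732224	76.8832222609	26.2664445219
F7	-65.400775165	47.5164445219	26.2664445219
F3	-39.0175950491	49.2965729646	57.2055519205
Fz	1.12487915223e-14	49.9617464449	68.7664445219
F4	39.0175950491	49.2965729646	57.2055519205
F8	65.400775165	47.5164445219	26.2664445219
FC5	-65.0916528747	25.5011018464	48.3504966951
FC1	-24.7426047354	26.1757819226	76.9911160567
FC2	24.7426047354	26.1757819226	76.9911160567
FC6	65.0916528747	25.5011018464	48.3504966951
T7	-80.8398038851	9.90002070716e-15	26.2664445219
C3	-49.9617464449	4.42742385597e-15	68.7664445219
Cz	4.38651478105e-31	1.04770588975e-30	85
C4	49.9617464449	-1.69112543038e-15	68.7664445219
T8	80.8398038851	-1.04770588975e-30	26.2664445219
CP5	-65.0916528747	-25.5011018464	48.3504966951
CP1	-24.7426047354	-26.1757819226	76.9911160567
CP2	24.7426047354	-26.1757819226	76.9911160567
CP6	65.0916528747	-25.5011018464	48.3504966951
AFz	0	68.7664445219	49.9617464449
P7	-65.400775165	-47.5164445219	26.2664445219
P3	-39.0175950491	-49.2965729646	57.2055519205
Pz	-5.95419124279e-15	-49.9617464449	68.7664445219
P4	39.0175950491	-49.2965729646	57.2055519205
P8	65.400775165	-47.5164445219	26.2664445219
PO9	-49.9617464449	-68.7664445219	5.20474889638e-15
O1	-24.9808732224	-76.8832222609	26.2664445219
Oz	-1.48500310607e-14	-80.8398038851	26.2664445219
O2	24.9808732224	-76.8832222609	26.2664445219
PO10	49.9617464449	-68.7664445219	5.20474889638e-15
AF7	-47.5164445219	65.400775165	26.2664445219
AF3	-26.6017272157	67.8775177153	43.7034403445
AF4	26.6017272157	67.8775177153	43.7034403445
AF8	47.5164445219	65.400775165	26.2664445219
F5	-54.4600616555	48.5165813526	43.6490895476
F1	-20.3498735679	49.7919440424	65.8152334513
F2	20.3498735679	49.7919440424	65.8152334513
F6	54.4600616555	48.5165813526	43.6490895476
FT7	-76.8832222609	24.9808732224	26.2664445219
FC3	-47.1458749812	25.9123659847	65.8089337501
FC4	47.1458749812	25.9123659847	65.8089337501
FT8	76.8832222609	24.9808732224	26.2664445219
C5	-68.7664445219	7.16372228156e-15	49.9617464449
C1	-26.2664445219	1.95897338519e-15	80.8398038851
C2	26.2664445219	-1.25773833568e-15	80.8398038851
C6	68.7664445219	-1.25773833568e-15	49.9617464449
TP7	-76.8832222609	-24.9808732224	26.2664445219
CP3	-47.1458749812	-25.9123659847	65.8089337501
CPz	-4.48294077695e-15	-26.2664445219	80.8398038851
CP4	47.1458749812	-25.9123659847	65.8089337501
TP8	76.8832222609	-24.9808732224	26.2664445219
P5	-54.4600616555	-48.5165813526	43.6490895476
P1	-20.3498735679	-49.7919440424	65.8152334513
P2	20.3498735679	-49.7919440424	65.8152334513
P6	54.4600616555	-48.5165813526	43.6490895476
PO7	-47.5164445219	-65.400775165	26.2664445219
PO3	-26.6017272157	-67.8775177153	43.7034403445
POz	-1.52882884179e-14	-68.7664445219	49.9617464449
PO4	26.6017272157	-67.8775177153	43.7034403445
PO8	47.5164445219	-65.400775165	26.2664445219
FCz	1.49431359232e-15	26.2664445219	80.8398038851
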