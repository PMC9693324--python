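BEGIN IONS
FEATURE_ID=lysopc_p180
NAME=lyso PC P-18:0
PEPMASS=508.3752
CHARGE=1+
86.0968 200000.0
104.1072 150000.0
124.9998 80000.0
184.0730 900000.0
240.0991 120000.0
END IONS

BEGIN IONS
FEATURE_ID=analog_507
PEPMASS=507.3549
CHARGE=1+
85.0764 200000.0
103.0868 150000.0
183.0526 900000.0
239.0786 120000.0
END IONS

BEGIN IONS
FEATURE_ID=analog_522
PEPMASS=522.3905
CHARGE=1+
98.0965 200000.0
116.1069 150000.0
196.0727 900000.0
252.0988 120000.0
END IONS
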