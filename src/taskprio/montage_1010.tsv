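channel	x	y	z
AF3	-0.314415	0.926952	0.204703
AF4	0.314415	0.926952	0.204703
AF7	-0.587785	0.809017	0.0
AF8	0.587785	0.809017	0.0
C1	-0.382683	-0.0	0.92388
C2	0.382683	0.0	0.92388
C3	-0.707107	-0.0	0.707107
C4	0.707107	0.0	0.707107
C5	-0.92388	-0.0	0.382683
C6	0.92388	0.0	0.382683
CP1	-0.340147	-0.452072	0.824579
CP2	0.340147	-0.452072	0.824579
CP3	-0.635947	-0.462522	0.617774
CP4	0.635947	-0.462522	0.617774
CP5	-0.848835	-0.412671	0.330427
CP6	0.848835	-0.412671	0.330427
CPz	0.0	-0.382683	0.92388
Cz	0.0	-0.0	1.0
F1	-0.250547	0.769492	0.587459
F2	0.250547	0.769492	0.587459
F3	-0.480804	0.769563	0.420238
F4	0.480804	0.769563	0.420238
F5	-0.672125	0.707314	0.218986
F6	0.672125	0.707314	0.218986
F7	-0.809017	0.587785	0.0
F8	0.809017	0.587785	0.0
FC1	-0.340147	0.452072	0.824579
FC2	0.340147	0.452072	0.824579
FC3	-0.635947	0.462522	0.617774
FC4	0.635947	0.462522	0.617774
FC5	-0.848835	0.412671	0.330427
FC6	0.848835	0.412671	0.330427
FT10	0.904508	0.293893	-0.309017
FT7	-0.951057	0.309017	0.0
FT8	0.951057	0.309017	0.0
FT9	-0.904508	0.293893	-0.309017
Fp1	-0.309017	0.951057	0.0
Fp2	0.309017	0.951057	0.0
Fz	0.0	0.707107	0.707107
O1	-0.309017	-0.951057	0.0
O2	0.309017	-0.951057	0.0
Oz	0.0	-1.0	0.0
P1	-0.250547	-0.769492	0.587459
P2	0.250547	-0.769492	0.587459
P3	-0.480804	-0.769563	0.420238
P4	0.480804	-0.769563	0.420238
P5	-0.672125	-0.707314	0.218986
P6	0.672125	-0.707314	0.218986
P7	-0.809017	-0.587785	0.0
P8	0.809017	-0.587785	0.0
PO10	0.559017	-0.769421	-0.309017
PO3	-0.314415	-0.926952	0.204703
PO4	0.314415	-0.926952	0.204703
PO7	-0.587785	-0.809017	0.0
PO8	0.587785	-0.809017	0.0
PO9	-0.559017	-0.769421	-0.309017
POz	0.0	-0.92388	0.382683
Pz	0.0	-0.707107	0.707107
T7	-1.0	-0.0	0.0
T8	1.0	0.0	0.0
TP10	0.904508	-0.293893	-0.309017
TP7	-0.951057	-0.309017	0.0
TP8	0.951057	-0.309017	0.0
TP9	-0.904508	-0.293893	-0.309017
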