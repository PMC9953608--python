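gene	cases_with	cases_without	controls_with	controls_without	published_p
ZFYVE26	7	28	0	38	0.0041
THSD7B	6	29	0	38	0.0095
SPATC1	6	29	0	38	0.0095
IGHG1	6	29	0	38	0.0095
EXO1	0	35	7	31	0.0119
JAKMIP3	9	26	2	36	0.0210
AHNAK	9	26	2	36	0.0210
PLEKHN1	5	30	0	38	0.0216
NBEAL2	5	30	0	38	0.0216
USP42	5	30	0	38	0.0216
OR4K1	5	30	0	38	0.0216
STARD9	5	30	0	38	0.0216
UNC13A	5	30	0	38	0.0216
OLFML2B	4	31	0	38	0.0481
MROH9	4	31	0	38	0.0481
SLC4A5	4	31	0	38	0.0481
VWA3B	4	31	0	38	0.0481
CAND2	4	31	0	38	0.0481
USP4	4	31	0	38	0.0481
LRP2BP	4	31	0	38	0.0481
ERAP2	4	31	0	38	0.0481
DOPEY1	4	31	0	38	0.0481
GLI3	4	31	0	38	0.0481
TRBV6-7	4	31	0	38	0.0481
LOXL2	4	31	0	38	0.0481
APOBEC1	4	31	0	38	0.0481
COL2A1	4	31	0	38	0.0481
LIMA1	4	31	0	38	0.0481
HAL	4	31	0	38	0.0481
RAI1	4	31	0	38	0.0481
MPP3	4	31	0	38	0.0481
RSAD1	4	31	0	38	0.0481
CILP2	4	31	0	38	0.0481
ZNF600	4	31	0	38	0.0481
LILRA4	4	31	0	38	0.0481
TUBB1	4	31	0	38	0.0481
UTRN	6	29	1	37	0.0497
NLRC3	6	29	1	37	0.0497
URB1	6	29	1	37	0.0497
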