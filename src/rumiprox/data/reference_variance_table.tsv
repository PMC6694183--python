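trait	factor	model_effects_current	model_effects_total	dependent_current	dependent_total
FCR	1	41.59	41.59	35.46	35.46
FCR	2	6.35	47.94	21.19	56.65
FCR	3	7.57	55.51	6.72	63.37
ADG	1	39.42	39.42	49.26	49.26
ADG	2	9.60	49.02	11.47	60.73
ADG	3	7.97	56.99	4.67	65.40
RFI	1	24.04	24.04	44.32	44.32
RFI	2	13.95	37.99	16.80	61.12
RFI	3	16.72	54.71	4.52	65.63
DFI	1	28.98	28.98	44.94	44.94
DFI	2	21.25	50.23	19.94	64.88
DFI	3	7.86	58.09	8.05	72.93
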