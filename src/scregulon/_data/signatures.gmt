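cytotoxicity	human CD8 cytotoxicity markers	GNLY	GZMB	PRF1
exhaustion	human CD8 inhibitory/exhaustion markers	HAVCR2	TIGIT
naiveness	human naive/stem-like markers (LEF1 plus CD62L/CCR7/TCF7 proxies for CD44lo CD62Lhi)	LEF1	SELL	CCR7	TCF7
murine_teff	murine terminal-effector signature	Ccl3	Cx3cr1	Gzma	Gzmb	Klra3	Klrg1	Prdm1	S1pr5
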