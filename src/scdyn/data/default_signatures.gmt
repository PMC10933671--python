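tfh	placeholder Tfh marker set (editable default; replace with your study's list)	CXCL13	PDCD1	BCL6	ICOS	CD200	TOX2	IL21
csps	placeholder cGAS-STING pathway seven-gene set (editable default)	CGAS	STING1	TBK1	IRF3	TREX1	IFI16	IKBKE
exhaustion	placeholder T-cell exhaustion set (editable default)	PDCD1	CTLA4	LAG3	HAVCR2	TIGIT	TOX	ENTPD1
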