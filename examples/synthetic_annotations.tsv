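# synthetic demonstration regulator->target annotations (not curated predictions)
hsa-miR-504	miRNA	BAK1
hsa-miR-504	miRNA	BCL2
hsa-miR-504	miRNA	E2F1
hsa-miR-504	miRNA	MCL1
hsa-miR-125a	miRNA	BAK1
hsa-miR-125a	miRNA	BCL2
hsa-miR-125a	miRNA	E2F2
hsa-miR-125a	miRNA	PIK3R5
AP-4	TF	BAD
AP-4	TF	BAK1
AP-4	TF	E2F2
AP-4	TF	PIK3R2
AP-4	TF	PIK3R5
E2F	TF	BCL2
E2F	TF	E2F1
E2F	TF	E2F2
E2F	TF	E2F3
E2F	TF	MYC
VDR	TF	AKT3
VDR	TF	BAX
VDR	TF	BECN1
VDR	TF	E2F2
hsa-miR-15a	miRNA	AKT3
hsa-miR-15a	miRNA	E2F3
hsa-miR-15a	miRNA	MYC
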