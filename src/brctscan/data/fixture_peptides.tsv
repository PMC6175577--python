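name	origin	peptide	site	compat_short	compat_long	strict	preferred
RHNO1-pT202	fp-assay	Fluorescein-GYGGPVLVKDpTPEDKYGI	11	BRCT1,BRCT2	BRCT1,BRCT2	BRCT1,BRCT2	BRCT1
Treslin-pT969	fp-assay	Fluorescein-GYGLTKSVAEpTPVHKQIS	11	BRCT2	BRCT1,BRCT2	BRCT2	none
Treslin-pS1001	fp-assay	Fluorescein-GYGDIGVVEEpSPEKGDEI	11	BRCT1,BRCT2	BRCT1,BRCT2	BRCT2	none
BLM-pS304	fp-assay	Fluorescein-GYGDTDFVPPpSPEEIISA	11	BRCT1,BRCT2	BRCT1,BRCT2	BRCT2	none
FANCJ-pT1133	fp-assay	Fluorescein-GYGEDESIYFpTPELYDPE	11	BRCT2	BRCT2	BRCT2	none
Mdb1-pT113	fp-assay	Fluorescein-GYGGVMTVPNpTPQKPNLQ	11	BRCT2	BRCT1,BRCT2	BRCT2	BRCT2
Mdb1-SDT-pS216	fp-assay	Fluorescein-GYGVEGDHSpSDpTEEEVVS	10	.	.	.	none
Mdb1-SDT-pT218	fp-assay	Fluorescein-GYGVEGDHSpSDpTEEEVVS	12	.	.	.	none
RAD9-pS387-crystal	crystallography	SPVLAEDpSEGE	8	BRCT1	BRCT1	.	BRCT1
Sld3-pT636	crystallography	GYDSILVQApTPRKSSSVITELPDpTPIKMNS	10	BRCT1,BRCT2	BRCT1,BRCT2	BRCT1,BRCT2	none
Sld3-pT650	crystallography	GYDSILVQApTPRKSSSVITELPDpTPIKMNS	24	BRCT2	BRCT2	BRCT2	BRCT2
Mdb1-pT113-crystal	crystallography	GVMTVPNpTPQKPNLQ	8	BRCT2	BRCT1,BRCT2	BRCT2	BRCT2
Crb2-pT235-like-synthetic	synthetic	GYGARLNDpTP	9	BRCT2	BRCT2	BRCT2	BRCT2
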