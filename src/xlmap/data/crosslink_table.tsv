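id	source	reliability	alpha_protein	alpha_seq	alpha_site	beta_protein	beta_seq	beta_site	n_ox	observed_mass_da	error_ppm
XL1	bpa_scan		ISWI_H483B	LDGQTPBEDRNR	483	ISWI	QTEIFTHFM[ox]TNSAK	59-60	1	3220.4946	-1.9
XL2	bpa_scan		ISWI_H483B	LDGQTPBEDRNR	483	ISWI	QTEIFTHFMTNSAK	60-61	0	3204.5056	-3.7
XL3	bpa_scan		ISWI_H483B	LDGQTPBEDR	483	ISWI	QTEIFTHFM[ox]TNSAK	55-59	1	2950.3474	-1.0
XL4	bpa_scan		ISWI_H483B	LDGQTPBEDR	483	ISWI	QTEIFTHFMTNSAK	59-61	0	2934.3571	-2.6
XL5	bpa_scan		ISWI_H483B	LDGQTPBEDRNR	483	ISWI	SPTKPK	69-72	0	2207.0968	0.2
XL6	bpa_scan		ISWI_H483B	LDGQTPBEDR	483	ISWI	SPTKPK	71-72	0	1936.9645	-6.1
XL7	bpa_scan		ISWI_H483B	LDGQTPBEDR	483	ISWI	GRPK	75	0	1736.8594	-6.1
XL11	h4_tail	high	H4_T1C	XGR	1	ISWI	QIQEFNMDNSAK	495	0	2034.8571	-0.2
XL12	h4_tail	high	H4_L10C	GXGK	10	SNF2H	VLDILEDYCMWR	520	0	2251.9753	-0.4
XL13a	h4_tail	high	H4_T1B	BGR	1	ISWI	LDGQTPHEDR	482	0	1648.7601	-0.4
XL13b	h4_tail	high	H4_T1B	BGR	1	ISWI	LDGQTPHEDRNR	482	0	1918.9052	-0.9
XL13c	h4_tail	high	H4_T1B	BGR	1	ISWI	LDGQTPHEDRNRQIQEFNM[ox]DNSAK	482	1	3340.5374	-2.8
XL14	h4_tail	medium	H4_T1C	XGR	1	SNF2H	VLDILEDYCMWR	519-522	0	2222.9624	-1.5
XL15	h4_tail	medium	H4_T1B	BGR	1	ISWI	M[ox]VIQGGR	578	1	1257.6261	2.3
XL16	h4_tail	medium	H4_T1B	BGR	1	ISWI	IVERAEVK	568	0	1424.7832	-3.9
XL17	h4_tail	medium	H4_L10B	GBGK	10	ISWI	IVERAEVK	568	0	1453.7998	-4.6
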