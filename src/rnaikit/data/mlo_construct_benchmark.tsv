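# Published evaluation series for RNAi constructs targeting the barley Mlo
# gene: per-construct siRNA hit counts predicted on the target (total, and
# the high-sensitivity / high-efficiency classification modes) alongside the
# experimentally measured mean log2 relative susceptibility index (mean_si)
# from transient silencing assays.  Used as a fixed evaluation vector for
# correlation analysis; the construct sequences themselves are an external
# deposition and are not shipped.
construct	total_hits	hs_hits	he_hits	mean_si
0MY	480	26	26	-1.36
1MY	304	150	15	-1.37
2MY	205	106	25	-1.61
3MY	149	76	13	-2.09
4MY	101	56	9	-1.14
5MY	59	21	0	-0.52
1-100W	80	41	0	-0.69
101-200W	80	39	7	-0.61
201-300W	81	37	7	-0.80
301-400W	80	39	1	-0.22
401-500W	80	40	10	-1.65
MloH1	22	17	4	-1.60
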