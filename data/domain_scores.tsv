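protein_id	gene	score_autoind_bind	score_gere_hth	score_autoind_synth
WP_002720271.1	cerR	128.1	63.4
WP_082242126.1	rs15160	77.1	68.2
WP_011336955.1	gtaR	51.6	24.6
WP_011338009.1	cerM	47.5	42.9
WP_002723109.1	15394	38.7	37.7
WP_009563908.1	cerN	66.1
WP_002720272.1	cerI			281.5
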