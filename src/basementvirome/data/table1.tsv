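# Published summary of fluid samples: analysis type, source location,
# collection method, Mg2+ concentration (mM), and epifluorescence counts
# (units of 1e4 per ml). Basement-fluid counts for the 2013-07-14 U1362B
# sample are for filtrate only, so its cell count is excluded from
# cell summaries (excluded_from_cells = 1).
sample_id	analysis	location	collection_method	mg_mM	virus_conc_1e4_per_ml	cell_conc_1e4_per_ml	excluded_from_cells
Meta-2011-07-10-U1362B	Meta	U1362B	in_situ_F				0
Meta-2011-07-12-U1362A	Meta	U1362A	in_situ_F				0
EfM-2013-07-14-U1362B	EfM	U1362B	MVBS	2.3-2.4	12.4	0.0	1
EfM-2013-07-15-U1362A	EfM	U1362A	MVBS	2.5-3.1	3.9	1.5	0
EfM-2013-07-21-U1362B	EfM	U1362B	LVBS	2.4	2.1	0.54	0
EfM-2014-08-15-U1362A	EfM	U1362A	LVBS	2.2	18	0.67	0
EfM-2014-08-22-U1362A-LVBS	EfM	U1362A	LVBS	2.5	8.1	0.78	0
EfM-2014-08-22-U1362A-MVBS	EfM	U1362A	MVBS	2.6	19	1.1	0
EfM-2014-08-09-U1362B-MVBS	EfM	U1362B	MVBS	2.2	2.8	1.3	0
EfM-2014-08-09-U1362B-LVBS	EfM	U1362B	LVBS	2.1	4.1	2.8	0
EfM-2014-08-11-nbSW	EfM	nbSW	Niskin	53.0	110	6.2	0
TEM-2014-08-15-U1362A	TEM	U1362A	in_situ_UF				0
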