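sample_id	species	subgenus	total_bp	lsc_bp	ssc_bp	ir_bp	gc_percent	accession
retroflexus	Amaranthus retroflexus	Amaranthus	150244	83605	17937	24351	36.6	MN091971
dubius	Amaranthus dubius	Amaranthus	150524	83880	17940	24352	36.6	MN091972
spinosus_113	Amaranthus spinosus	Amaranthus	150523	83879	17940	24352	36.6	MT526784
spinosus_11902	Amaranthus spinosus	Amaranthus	150524	83880	17940	24352	36.6	MT526783
hypochondriacus	Amaranthus hypochondriacus	Amaranthus	150523	83878	17941	24352	36.6	MG836505
hybridus	Amaranthus hybridus	Amaranthus	150690	84062	17948	24340	36.6	MT559305
palmeri	Amaranthus palmeri	Acnida	150731	84010	18027	24347	36.6	MN091990
arenicola_JSTZ	Amaranthus arenicola	Acnida	150632	83901	18039	24346	36.6	MN091969
arenicola_HBTS	Amaranthus arenicola	Acnida	150630	83899	18039	24346	36.6	MZ152791
tuberculatus_GZW	Amaranthus tuberculatus	Acnida	150679	83945	18042	24346	36.6	MT559304
tuberculatus_11994	Amaranthus tuberculatus	Acnida	150695	83961	18042	24346	36.6	MN091967
tuberculatus_12194	Amaranthus tuberculatus	Acnida	150696	83962	18042	24346	36.6	MN091968
blitum	Amaranthus blitum	Albersia	150621	83806	18057	24379	36.6	MT526777
crispus	Amaranthus crispus	Albersia	150567	83793	18060	24357	36.6	MT526778
standleyanus_11960	Amaranthus standleyanus	Albersia	150567	83793	18060	24357	36.6	MT526781
standleyanus_7433	Amaranthus standleyanus	Albersia	150568	83794	18060	24357	36.6	MT526782
tunetanus	Amaranthus tunetanus	Albersia	150581	83805	18062	24357	36.6	MT526780
deflexus	Amaranthus deflexus	Albersia	150256	83489	18065	24351	36.6	MT526776
capensis	Amaranthus capensis	Albersia	150707	83928	18075	24352	36.6	MT526779
blitoides	Amaranthus blitoides	Albersia	150667	83878	18089	24350	36.5	MT526786
albus	Amaranthus albus	Albersia	150756	83943	18111	24351	36.5	MT526785
polygonoides	Amaranthus polygonoides	Albersia	149948	83896	18124	23964	36.5	MT472619
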