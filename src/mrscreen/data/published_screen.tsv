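direction	taxon_level	taxon_id	exposure	outcome	or	ci_low	ci_high	pvalue
forward	genus	id.1837	Lactobacillus	FT4	0.919	0.847	0.996	0.040
forward	genus	id.11321	Lachnospiraceae UCG-001	FT4	0.943	0.891	0.998	0.043
forward	genus	id.11342	Ruminococcus gauvreauii group	FT4	0.922	0.860	0.988	0.021
forward	genus	id.2070	Subdoligranulum	FT4	1.123	1.039	1.214	0.003
forward	order	id.3468	Enterobacteriales	TSH	1.122	1.032	1.220	0.007
forward	family	id.3469	Enterobacteriaceae	TSH	1.122	1.032	1.220	0.00711
forward	genus	id.2198	Veillonella	TSH	1.078	1.005	1.155	0.034
forward	family	id.1987	Lachnospiraceae	TSH	0.941	0.889	0.997	0.0384
forward	genus	id.2064	Oscillospira	TSH	0.911	0.848	0.979	0.011
forward	order	id.11579	Mollicutes RF9	hypothyroidism	1.092	1.015	1.173	0.018
forward	genus	id.3173	Desulfovibrio	hypothyroidism	1.087	1.009	1.172	0.028
forward	genus	id.2062	Intestinimonas	hypothyroidism	1.096	1.032	1.164	0.003
forward	genus	id.11355	Ruminiclostridium 5	hypothyroidism	1.099	1.005	1.202	0.039
forward	genus	id.11363	Ruminococcaceae UCG-005	hypothyroidism	1.097	1.002	1.202	0.045
forward	phylum	id.400	Actinobacteria	hypothyroidism	0.883	0.817	0.955	0.002
forward	family	id.2875	Alcaligenaceae	hypothyroidism	0.894	0.815	0.981	0.018
forward	family	id.1924	Defluviitaleaceae	hypothyroidism	0.926	0.869	0.987	0.019
forward	genus	id.1993	Butyrivibrio	hypothyroidism	0.956	0.924	0.989	0.009
forward	genus	id.819	Eggerthella	hypothyroidism	0.941	0.891	0.994	0.030
forward	genus	id.11328	Lachnospiraceae UCG-008	hypothyroidism	0.909	0.841	0.983	0.017
forward	order	id.11579	Mollicutes RF9	hyperthyroidism	1.497	1.107	2.025	0.009
forward	genus	id.11362	Ruminococcaceae UCG-004	hyperthyroidism	1.384	1.016	1.884	0.039
forward	genus	id.11358	Ruminococcaceae NK4A214 group	hyperthyroidism	1.502	1.058	2.131	0.023
forward	genus	id.11182	Prevotella 7	hyperthyroidism	1.259	1.023	1.549	0.030
forward	genus	id.815	Collinsella	hyperthyroidism	1.858	1.184	2.916	0.007
forward	genus	id.2153	Catenibacterium	hyperthyroidism	1.437	1.057	1.954	0.021
forward	genus	id.3170	Bilophila	hyperthyroidism	1.486	1.043	2.118	0.028
forward	phylum	id.3982	Verrucomicrobia	hyperthyroidism	0.697	0.508	0.957	0.026
forward	class	id.3087	Deltaproteobacteria	hyperthyroidism	0.549	0.374	0.805	0.002
forward	family	id.3169	Desulfovibrionaceae	hyperthyroidism	0.621	0.403	0.956	0.031
forward	family	id.917	Bacteroidaceae	hyperthyroidism	0.552	0.345	0.882	0.013
forward	genus	id.2892	Parasutterella	hyperthyroidism	0.717	0.546	0.941	0.016
forward	genus	id.918	Bacteroides	hyperthyroidism	0.552	0.345	0.882	0.013
reverse	order	id.11579	hyperthyroidism	Mollicutes RF9	1.067	1.0003	1.138	0.0488
reverse	genus	id.11363	hypothyroidism	Ruminococcaceae UCG-005	1.038	1.001	1.078	0.0497
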