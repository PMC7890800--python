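# somafilt ICGC-recommendation filter preset (reconstructed; name<TAB>threshold)
min_depth_tumor	25
min_depth_normal	25
min_alt_count_tumor	3
min_vaf_tumor	0.05
max_vaf_normal	0.02
max_alt_count_normal	0
min_median_bq_alt_tumor	25
min_median_mq_alt_tumor	30
strand_minor_frac_alt_tumor	0.01
min_median_dist_readend_alt_tumor	10
min_mad_pos_alt_tumor	3
max_softclip_frac_alt_tumor	0.3
max_excess_nm_alt_tumor	2
max_mq0_frac_tumor	0.1
max_near_indel_frac_tumor	0.3
max_improper_pair_frac_alt_tumor	0.5
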