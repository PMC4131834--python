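key	value
kn_snp_total	2787250
kn_indel_total	7393
k93_snp_total	2216251
k93_indel_total	3780
kn_alignment_bp	278750000
k93_alignment_bp	259000000
kn_snp_freq_pct	1.00
k93_snp_freq_pct	0.86
kn_mean_indel_bp	1999
k93_mean_indel_bp	735
kn_del_sites	5026
kn_del_mb	13.49
kn_ins_sites	2367
kn_ins_mb	1.29
kn_indel_total_mb	14.78
k93_del_sites	2244
k93_del_mb	1.84
k93_ins_sites	1536
k93_ins_mb	0.94
total_contigs	51550
total_assembly_mb	330.55
unmapped_mean_bp	2749
mapped_mean_bp	7847
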