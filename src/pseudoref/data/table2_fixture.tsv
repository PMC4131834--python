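chrom	kn_snps	kn_indels	k93_snps	k93_indels
chr01	318375	921	252557	506
chr02	253524	651	184485	383
chr03	278482	749	204712	405
chr04	233426	617	212291	329
chr05	244149	616	179973	294
chr06	241274	648	210155	373
chr07	231566	605	155910	300
chr08	214710	535	166666	255
chr09	179050	434	141896	232
chr10	193491	531	149212	241
chr11	211931	533	185340	195
chr12	187272	553	173054	267
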