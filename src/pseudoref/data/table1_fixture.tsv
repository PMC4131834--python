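row	n_contigs	n50_bp	max_bp	printed_mean_bp	total_bp
mapped	36936	13728	103131	7847	289796664
unmapped	14822	3615	43777	2749	40748813
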