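# Published six-method MOTU counts for the 28 Molytinae weevil morphospecies
# flagged for possible cryptic diversity or population divergence in a COI
# barcode comparison.  max_intra_pct is the maximum intraspecific K2P
# distance in percent.
species	n_seqs	abgd	asap	bin	bptp	jmotu	ptp	max_intra_pct
Aclees cribratus	7	5	5	6	6	6	6	27.5
Aethiopacorep africanus	6	3	3	4	3	3	3	10.7
Aparopionella ombrophila	8	2	2	3	3	2	3	7.1
Conotrachelus anaglypticus	11	2	2	2	2	2	2	12.3
Devernodes alkippe	12	2	2	2	2	2	2	8.6
Etheophanus striatus	50	2	2	9	4	2	5	11.2
Lepyrus labradorensis	16	2	2	2	2	2	2	7.6
Lepyrus nordenskioeldi	2	2	2	2	2	2	2	12.2
Lupangus jason	7	2	2	2	2	2	2	7.9
Lybaeba sp. SPN41	26	3	3	4	5	3	4	14.2
Lybaeba sp. SPN53	3	3	3	3	3	3	3	12.6
Melanterius servulus	28	3	3	3	3	3	3	15.3
Melanterius sp. SPN63	2	2	2	2	2	2	2	17.6
Melanterius sp. SPN73	2	2	2	2	2	2	2	11.5
Melanterius sp. SPN78	6	2	2	2	2	2	2	11.7
Morimotodes ismene	34	7	7	7	7	7	7	19.1
Otibazo morimotoi	17	2	2	4	4	2	4	15.5
Peribleptus foveostriatus	15	2	2	2	2	2	2	7.5
Peribleptus scalptus	7	2	2	2	2	2	2	8.3
Pissodes rotundatus	9	2	2	4	3	2	3	13.2
Pissodes strobi	4	2	2	2	2	2	2	8.2
Tazarcus aeaea	2	2	2	2	2	2	2	15.1
Typoderus admetus	55	4	2	10	6	3	6	10.7
Typoderus furcatus	13	2	2	3	3	2	3	8.0
Typoderus iphitus	3	2	2	2	2	2	2	10.6
Typoderus peleus	12	3	3	4	4	3	3	12.7
Typoderus sp. VG1808	12	2	2	5	5	2	3	12.1
Typoderus subfurcatus	24	6	6	9	10	6	10	18.3
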