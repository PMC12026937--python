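# Small default motif set (synthetic): short patterns echoing recurrent
# RNA sequence/interaction motifs (tetraloops, E-loop and kink-turn-like
# tandem purine patterns, gapped two-part motifs).  IUPAC codes; '*'
# matches one or more nucleotides.
gnra_tetraloop	GNRA
uncg_tetraloop	UNCG
cuug_tetraloop	CUUG
e_loop	AGUA
tandem_ga	GAGA
uc_ga_gapped	UC*GA
ga_ga_gapped	GA*GA
ur_gap_ya	URC*GYA
purine_rich	RRAG
pyrimidine_rich	YYCU
# Composition runs: keto (G/U) runs are enriched in paired strands
# (canonical pairs always involve G or U on one side, and wobble pairs
# on both), amino (A/C) runs in unpaired regions.
keto_run	KKKKK
amino_run	MMMMM
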