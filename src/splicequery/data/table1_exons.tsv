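transcript_id	gene	exon_label	coord_a	coord_b
KCNJ6-201	KCNJ6	E1	37961457	37915884
KCNJ6-201	KCNJ6	E2	37840709	37840658
KCNJ6-201	KCNJ6	E3	37715131	37714211
KCNJ6-201	KCNJ6	E4	37625484	37607373
KCNJ6-202	KCNJ6	E1b	38121345	38121128
KCNJ6-202	KCNJ6	E1bis	38120408	38120307
KCNJ6-202	KCNJ6	E2	37840709	37840658
KCNJ6-202	KCNJ6	E3	37715131	37714211
KCNJ6-202	KCNJ6	E4b	37625484	37623559
DSCR4-201	DSCR4	E1	38121360	38121128
DSCR4-201	DSCR4	E2	38120408	38120307
DSCR4-201	DSCR4	E3	38054773	38054011
DSCR4-202	DSCR4	E1	38121360	38121128
DSCR4-202	DSCR4	E2	38120408	38120307
DSCR4-202	DSCR4	E3	37953005	37952821
DSCR4-202	DSCR4	E4	37951702	37951425
DSCR4-203	DSCR4	E1	38121360	38121128
DSCR4-203	DSCR4	E2	38120408	38120307
DSCR4-203	DSCR4	E3	38099338	38099277
DSCR4-203	DSCR4	E4	38097509	38097267
DSCR4-203	DSCR4	E5	38094840	38094758
DSCR4-203	DSCR4	E6	38093348	38093244
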