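no	location	loop_motif	size	upstream_stem	downstream_stem
1	psbA-trnH	tgat	4	tcaataccaaacttct	agaagtttggtattga
2	rps16 intron	cttacttcctgaag	14	ttttttttttttttt	aaaaaaaaaaaaaaa
3	trnG-trnR	cacactttcccatttccgaaaggaaatggaatcagattgtatgtg	45	atttttttttttt	aaaaaaaaaaaat
4	atpA-trnR	aa	2	attttt	aaaaat
5	rpoB-trnC	caa	3	catgtttttttttttttttcttt	aaagaaaaaaaaaaaaaaacatg
6	psbM-trnD	ga	2	aaaaa	aaaaa
7	psbC-trnS	tcccacc	7	ggctcggcta	tagccgagcc
8	atpE-trnM	tttgtttatagaacttatttgggtattgactcc	33	aacttattagatacc	ggtatctaataagtt
9	accD-rbcL	tag	3	tcttctatt	aatagaaga
10	accD	ttct	4	aactagaaaa	ttttctagtt
11	accD-psaI	tcc	3	ttccat	atggaa
12	petA-psbJ	ggaattttgcaccc	14	tttcgacacaagaaaa	ttttcttgtgtcgaaa
13	petA-psbJ	ggagatgatttcttgaacaaatagaacttcttcaatgaacc	41	aaaaaaaaaaaaa	ttttttttttttt
14	petA-psbJ	ttt	3	gatg	catc
15	petL-psbE	atgccatggttactcc	16	aaatccaattctttt	aaaagaattggattt
16	clpP intron	ctt	3	ttttttttt	aaaaaaaaa
17	psbN-psbT	cgtatg	6	taattgaagtaatgagccccc	gggggctcattacttcaatta
18	petD-rpoA	aaa	3	tcttttttttt	aaaaaaaaaga
19	ycf2	aa	2	tttcattc	gaatgaaa
20	ycf2	tc	2	caaatac	aattttg
21	rpl32-trnL	ttttttttttt	11	tctaactcttttttcttt	aaagaaaaaagagttaga
22	rpl32-trnL	cttttagatctttgataccaaccaaatatttatagaaactttttgg	46	tcattactacat	atgtagtaatga
23	ccsA-psaC	atc	3	aat	att
24	rps7-trnH	aac	3	agaatgaa	ttcattct
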