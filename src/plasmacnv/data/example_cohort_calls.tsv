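# Worked-example cohort: screen-positive subjects from a published 64-sample plasma-DNA
# case-control study of high-grade serous ovarian carcinoma (32 cases: 16 FIGO I-II "early",
# 16 FIGO III-IV "advanced"; 32 benign controls). One row per reported >=15 Mb copy-number
# call; whole-chromosome entries are expanded to the chromosome arms covering >=25% of the
# event under the bundled genome's centromeres. Subjects absent from this file screened
# negative. aneuploidy_call is the whole-chromosome NIPT-pipeline result for the subject.
subject	group	stage	aneuploidy_call	direction	arms	label
S01	early_cancer	2C	no_call	gain	3q	3q gain
S01	early_cancer	2C	no_call	gain	12p	12p gain
S01	early_cancer	2C	no_call	gain	20q	20q terminal gain
S01	early_cancer	2C	no_call	loss	5q	5q segmental loss
S01	early_cancer	2C	no_call	loss	8p	8p loss
S01	early_cancer	2C	no_call	loss	9p	9p loss
S01	early_cancer	2C	no_call	gain	5p	5p gain
S01	early_cancer	2C	no_call	loss	7q	7q segmental loss
S02	early_cancer	2C	no_call	gain	3q	3q terminal gain
S02	early_cancer	2C	no_call	gain	20p,20q	chr20 gain
S02	early_cancer	2C	no_call	loss	4q	4q loss
S02	early_cancer	2C	no_call	loss	7p	7p loss
S02	early_cancer	2C	no_call	loss	13q	13q segmental loss
S02	early_cancer	2C	no_call	loss	15q	15q segmental loss
S02	early_cancer	2C	no_call	gain	6p	6p gain
S02	early_cancer	2C	no_call	gain	2q	2q interstitial gain
S02	early_cancer	2C	no_call	gain	18q	18q segmental gain
S03	early_cancer	1C	low_risk	gain	12p	12p terminal gain
S04	early_cancer	2C	low_risk	gain	3q	3q interstitial gain
S04	early_cancer	2C	low_risk	gain	8q	8q gain
S05	early_cancer	1C	low_risk	gain	8q	8q terminal gain
S05	early_cancer	1C	low_risk	gain	3p	3p terminal gain
S06	early_cancer	2A	low_risk	gain	8q	8q terminal gain
S07	advanced_cancer	4	no_call	gain	3q	3q terminal gain
S07	advanced_cancer	4	no_call	gain	8p,8q	chr8 gain
S07	advanced_cancer	4	no_call	loss	5q	5q loss
S07	advanced_cancer	4	no_call	loss	13q	chr13 loss
S07	advanced_cancer	4	no_call	loss	15q	chr15 loss
S07	advanced_cancer	4	no_call	loss	17p,17q	chr17 loss
S07	advanced_cancer	4	no_call	loss	18q	chr18 loss
S07	advanced_cancer	4	no_call	loss	22p,22q	chr22 loss
S07	advanced_cancer	4	no_call	loss	14q	chr14 loss
S07	advanced_cancer	4	no_call	gain	5p	5p gain
S07	advanced_cancer	4	no_call	gain	9p	9p gain
S08	advanced_cancer	3B	low_risk	gain	8q	8q terminal gain
S08	advanced_cancer	3B	low_risk	loss	8p	8p terminal loss
S08	advanced_cancer	3B	low_risk	gain	1q	1q interstitial gain
S08	advanced_cancer	3B	low_risk	gain	6p	6p gain
S08	advanced_cancer	3B	low_risk	gain	1p	1p interstitial gain
S08	advanced_cancer	3B	low_risk	gain	11q	11q segmental gain
S09	advanced_cancer	3A1	low_risk	gain	20p,20q	chr20 gain
S10	advanced_cancer	3A	low_risk	gain	11q	11q interstitial gain
S11	advanced_cancer	3C	no_call	gain	8q	8q terminal gain
S11	advanced_cancer	3C	no_call	gain	12p	12p terminal gain
S11	advanced_cancer	3C	no_call	loss	4q	4q segmental loss
S11	advanced_cancer	3C	no_call	loss	5q	5q interstitial loss
S11	advanced_cancer	3C	no_call	loss	6q	6q terminal loss
S11	advanced_cancer	3C	no_call	loss	8p	8p loss
S11	advanced_cancer	3C	no_call	loss	9p	9p terminal loss
S11	advanced_cancer	3C	no_call	loss	13q	13q segmental loss
S11	advanced_cancer	3C	no_call	loss	15q	15q segmental loss
S11	advanced_cancer	3C	no_call	loss	17q	17q segmental loss
S11	advanced_cancer	3C	no_call	loss	22p,22q	chr22 loss
S11	advanced_cancer	3C	no_call	gain	6p	6p segmental gains
S11	advanced_cancer	3C	no_call	gain	7q	7q segmental gains
S11	advanced_cancer	3C	no_call	gain	1p	1p segmental gains
S11	advanced_cancer	3C	no_call	gain	2p,2q	chr2 segmental gains
S11	advanced_cancer	3C	no_call	gain	5p	5p gain
S11	advanced_cancer	3C	no_call	gain	11q	11q interstitial gain
S11	advanced_cancer	3C	no_call	gain	18q	18q segmental gain
S11	advanced_cancer	3C	no_call	loss	1p	1p segmental loss
S11	advanced_cancer	3C	no_call	loss	10p	10p loss
S11	advanced_cancer	3C	no_call	loss	11q	11q terminal loss
S11	advanced_cancer	3C	no_call	loss	21p,21q	chr21 loss
S12	advanced_cancer	3C	no_call	gain	3q	3q gain
S12	advanced_cancer	3C	no_call	loss	4p	4p loss
S12	advanced_cancer	3C	no_call	loss	9q	9q loss
S12	advanced_cancer	3C	no_call	loss	13q	chr13 loss
S12	advanced_cancer	3C	no_call	gain	1q	1q gain
S12	advanced_cancer	3C	no_call	gain	6p	6p gain
S12	advanced_cancer	3C	no_call	gain	7q	7q terminal gain
S12	advanced_cancer	3C	no_call	loss	11p	11p loss
S12	advanced_cancer	3C	no_call	loss	5p	5p loss
S12	advanced_cancer	3C	no_call	loss	7p	7p terminal loss
S12	advanced_cancer	3C	no_call	gain	10p	10p gain
S12	advanced_cancer	3C	no_call	gain	18q	chr18 gain
S13	advanced_cancer	3C	monosomy 18	gain	20q	20q gain
S13	advanced_cancer	3C	monosomy 18	gain	8q	8q terminal segmental gain
S14	control	NA	low_risk	gain	20q	20q segmental gain
S15	control	NA	low_risk	gain	20q	20q gain
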