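study_id	accession	platform	tissue	n_control	n_iugr	n_pe
Dunk2012	GSE25861	Affymetrix	Isolated PIMEC	3	6	
Nishizawa2010	GSE24129	Affymetrix	Placenta	8	8	8
Sitras2008	GSE12216	Applied Biosystems	Placenta	8	8	
Tsai2010	GSE25906	BeadArray	Placenta	37		23
Winn2009	GSE14722	Affymetrix	Placenta	11		12
Guo2012	GSE35574	Illumina	Placenta	40	27	19
Guo2011	GSE24818	Agilent	Umbilical cord	22	18	
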