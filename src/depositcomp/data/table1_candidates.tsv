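description	accession
Small ubiquitin-related modifier 3 (SUMO3)	P55854
Thioredoxin (TXN)	P10599
Ubiquitin-40S ribosomal protein S27a (RPS27A)	P62979
Histone H2B type 1-A (H2BC1)	Q96A08
Claudin-11 (CLDN11)	O75508
Sodium/hydrogen exchanger 1 (SLC9A1)	P19634
Hemogen (HEMGN)	Q9BXL5
Hornerin (HRNR)	Q86YZ3
Syntaxin-binding protein 5-like (STXBP5L)	Q9Y2K9
Inter-alpha-trypsin inhibitor heavy chain (ITIH5)	Q86UX2
Leucine-rich repeat and IQ domain-containing protein 1 (LRRIQ1)	Q96JM4
Neuroblastoma breakpoint family member 19 (NBPF19)	A0A087WUL8
Actin, aortic smooth muscle (ACTA2)	P62736
Potassium-transporting ATPase alpha chain 1 (ATP4A)	P20648
Guanine nucleotide-binding protein G(s) subunit alpha isoforms XLas (GNAS)	Q5JWF2
Tubulin alpha-1B chain (TUBA1B)	P68363
Hemoglobin subunit beta (HBB)	P68871
Decorin (DCN)	P07585
Creatine kinase U-type, mitochondrial (CKMT1A)	P12532
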