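gene_id	biotype	rank
Cst9	protein_coding	1
Cox8c	protein_coding	2
Ddx4	protein_coding	3
Tuba3b	protein_coding	4
Rbakdn	lncRNA	5
4930449C09Rik	lncRNA	6
Pttg1ip2	protein_coding	7
Capza3	protein_coding	8
Prr27	protein_coding	9
Piwil1	protein_coding	10
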