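# Known genes in the three translocation-breakpoint windows (Hg19, 1-based inclusive)
# with the observed BEC40W/BEC20W signed fold changes in FPKM transcript levels.
# coords_source: "catalog" = coordinates as catalogued for the study;
# "refseq_hg19" = PLA2G15, reported by fold change only, coordinates taken from
# the Hg19 RefSeq annotation.
gene_id	window	chrom	start	end	fold_change	coords_source
FNDC4	2p22	2	27714749	27718126	2.2	catalog
GCKR	2p22	2	27719705	27746550	-81.4	catalog
RBKS	2p22	2	28004265	28561767	20.6	catalog
FOSL2	2p22	2	28615778	28637516	2.9	catalog
SPDYA	2p22	2	29033699	29093175	2.7	catalog
FAM179A	2p22	2	29204163	29275096	50.6	catalog
CLIP4	2p22	2	29338307	29406679	2.0	catalog
YPEL5	2p22	2	30369749	30383399	2.9	catalog
LBH	2p22	2	30454396	30482899	2.6	catalog
GALNT14	2p22	2	31133332	31361571	-20.6	catalog
CAPN14	2p22	2	31395921	31440411	-6.6	catalog
XDH	2p22	2	31557187	31637611	-4.8	catalog
NLRC4	2p22	2	32449517	32490812	-3.2	catalog
RASGRP3	2p22	2	33661415	33789798	2.9	catalog
MBL1P	10q22	10	81664653	81691557	-52.5	catalog
LDB3	10q22	10	88428205	88495824	-39.2	catalog
MMRN2	10q22	10	88695297	88717425	4.9	catalog
SNCG	10q22	10	88718287	88723017	15.9	catalog
AGAP11	10q22	10	88728187	88769960	6.9	catalog
FAM25A	10q22	10	88780045	88784487	430.4	catalog
FAM22D	10q22	10	89117476	89130452	3.7	catalog
PAPSS2	10q22	10	89419475	89507462	2.7	catalog
ANKRD22	10q22	10	90562486	90611732	17.9	catalog
STAMBPL1	10q22	10	90640025	90683244	20.0	catalog
RRAD	16q22	16	66955581	66959439	2.5	catalog
CES2	16q22	16	66968346	66978994	2.4	catalog
CES4A	16q22	16	67022491	67043659	-20.3	catalog
B3GNT9	16q22	16	67143914	67184902	2.5	catalog
TRADD	16q22	16	67188088	67193812	3.2	catalog
HSF4	16q22	16	67193890	67203848	6.7	catalog
ELMO3	16q22	16	67233027	67237927	3.3	catalog
LRRC29	16q22	16	67241041	67260901	56.6	catalog
FHOD1	16q22	16	67263291	67281425	-2.8	catalog
SLC9A5	16q22	16	67282854	67306094	3.4	catalog
HSD11B2	16q22	16	67465035	67471454	3.4	catalog
ACD	16q22	16	67679029	67694718	3.9	catalog
PARD6A	16q22	16	67694850	67696681	-64.3	catalog
SLC12A4	16q22	16	67973786	68002597	2.7	catalog
ESRP2	16q22	16	68119268	68270136	2.8	catalog
PLA2G15	16q22	16	68279266	68305079	2.1	refseq_hg19
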