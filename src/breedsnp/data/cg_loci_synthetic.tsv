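#gene	chrom	start	end
# SYNTHETIC fixture: 76 bovine growth/development candidate-gene loci with
# approximate UMD3.1-scale coordinates, shipped as a user-replaceable schema
# example for interval-based SNP hit counting. Gene symbols are real; the
# coordinates are plausible stand-ins, not curated annotation.
KCNIP4	6	63050000	64230000
CCSER1	6	86900000	88380000
DPP6	4	113900000	114920000
MAP3K5	9	81950000	82180000
GHR	20	31890000	32200000
CAST	7	98400000	98530000
GH1	19	48760000	48770000
GHRHR	4	84210000	84230000
GHSR	1	80410000	80420000
GHRL	22	52300000	52310000
IGF1	5	66530000	66610000
IGF1R	21	7950000	8260000
IGF2	29	49500000	49530000
IGF2R	9	96200000	96330000
IGFBP2	2	105700000	105730000
IGFBP3	4	42620000	42640000
IGFBP4	19	43220000	43240000
IGFBP5	2	105800000	105830000
INSR	7	17750000	17910000
INS	29	49540000	49550000
LEP	4	93240000	93260000
LEPR	3	80300000	80520000
MSTN	2	6210000	6220000
MYF5	5	31620000	31630000
MYF6	5	31640000	31650000
MYOD1	15	76290000	76300000
MYOG	16	72700000	72710000
MEF2C	7	55100000	55270000
FST	20	69900000	69910000
DGAT1	14	1790000	1810000
SCD	26	21140000	21160000
FABP4	14	46830000	46840000
FASN	19	51380000	51400000
PPARG	22	57590000	57720000
PPARGC1A	6	44850000	45520000
ADIPOQ	1	71660000	71680000
NPY	4	81340000	81350000
POMC	11	72100000	72110000
MC4R	24	59800000	59810000
AGRP	18	23580000	23590000
CARTPT	20	22600000	22610000
CAPN1	29	44060000	44090000
CAPN2	16	28620000	28690000
CAPN3	10	37400000	37450000
TG	14	9270000	9540000
DES	2	106200000	106210000
ACTA1	28	8120000	8130000
TNNT3	29	50120000	50140000
CKM	18	50680000	50700000
SST	1	79600000	79610000
SSTR2	19	56100000	56110000
PRL	23	35100000	35110000
PRLR	20	39100000	39280000
POU1F1	1	34750000	34770000
PROP1	7	41200000	41210000
TRH	22	11300000	11310000
TSHB	3	33300000	33310000
TSHR	10	85400000	85580000
CGA	9	38500000	38520000
LHB	18	57120000	57130000
FSHB	15	63800000	63810000
GNRH1	27	33900000	33910000
GNRHR	6	93400000	93420000
KISS1	16	29000000	29010000
ESR1	9	91200000	91500000
AR	X	86100000	86280000
CRH	14	65800000	65810000
NR3C1	7	76900000	77050000
STAT5A	19	43040000	43070000
STAT5B	19	42970000	43030000
JAK2	8	41500000	41650000
SOCS2	5	73500000	73530000
PLAG1	14	25000000	25050000
NCAPG	6	38750000	38800000
LCORL	6	38830000	38930000
HMGA2	5	47850000	48000000
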