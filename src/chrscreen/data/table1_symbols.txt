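ADSS
ANLN
ANP32E
ARHGAP11A
ARHGAP11B
ARL13B
ARL6IP1
ASF1B
ASPM
ATAD2
AURKA
AURKB
BIRC5
BORA
BUB1
BUB1B
C11orf82
C12orf32
C15orf42
C2orf69
C3orf26
C9orf100
CACYBP
CASC5
CBX3
CCDC150
CCDC18
CCDC34
CCDC99
CCNA2
CCNB1
CCNB2
CDC20
CDC25A
CDC25B
CDC25C
CDC7
CDCA2
CDCA3
CDCA5
CDCA8
CDK1
CDK2
CDKN3
CENPA
CENPE
CENPF
CENPL
CENPM
CENPN
CENPO
CEP152
CEP55
CHEK2
CIT
CKAP2L
CKAP5
CKS1B
CKS2
CSE1L
CSTF1
CTDSPL2
DARS2
DBF4B
DCAF16
DCK
DCLRE1B
DDX10
DEPDC1
DEPDC1B
DLEU1
DLGAP5
ESCO2
ESPL1
EXOSC8
EXOSC9
FAM64A
FAM83D
FANCB
FBXO5
FOXM1
GAS2L3
GSG2
GTSE1
H2AFX
H2AFZ
HAUS8
HIST1H2AE
HIST1H2AM
HIST1H2BF
HIST1H2BH
HIST1H2BI
HIST1H2BM
HIST1H2BN
HIST1H3C
HIST1H3D
HIST1H4C
HIST2H2AB
HIST2H2AC
HJURP
HMGB2
HMMR
HNRNPA0
HNRNPA2B1
HNRNPUL1
IFT80
INCENP
ING1
ING3
IQGAP3
KIAA1731
KIF11
KIF14
KIF15
KIF18A
KIF20A
KIF20B
KIF22
KIF23
KIF24
KIF2C
KIF4A
KIFC1
KPNB1
LIN54
LIN9
LMNB1
LRRC49
LSM5
MAD2L1
MASTL
MCM5
MCM7
MCM8
MDC1
MELK
METTL13
METTL4
MIS18BP1
MKI67
MND1
MTF2
MYBL2
NASP
NCAPD2
NCAPD3
NCAPG
NCAPG2
NCAPH
NDC80
NEIL3
NET1
NUF2
NUP107
NUP205
NUP35
NUSAP1
OIP5
ORC1
PCNT
PLK1
PLK4
POC5
POLD1
POLQ
POP7
PPIH
PRC1
PRIM2
PRPF38A
PRR11
PTTG1
RACGAP1
RAD18
RAD21
RAD54L
RANGAP1
RBM15
RBMX
REEP4
RIF1
RNASEH2A
RTKN2
SASS6
SCLT1
SGOL1
SGOL2
SHCBP1
SLC25A40
SMC2
SMC4
SNRPA
SP4
SPAG5
SPC25
STIL
SUZ12
TCERG1
TMEM48
TMPO
TPX2
TRAIP
TROAP
TTK
UBE2C
UBE2S
UNG
USP1
YEATS4
ZNF367
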