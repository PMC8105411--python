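condition,gene
CX-5461 (IC50),ALKBH1
CX-5461 (IC50),ATM
CX-5461 (IC50),ATR
CX-5461 (IC50),BARD1
CX-5461 (IC50),BRCA2
CX-5461 (IC50),H2AFX
CX-5461 (IC50),LIG4
CX-5461 (IC50),MMS22L
CX-5461 (IC50),MUS81
CX-5461 (IC50),OXR1
CX-5461 (IC50),PALB2
CX-5461 (IC50),POLH
CX-5461 (IC50),POLQ
CX-5461 (IC50),PSMB4
CX-5461 (IC50),PSMC4
CX-5461 (IC50),PSMC5
CX-5461 (IC50),RAD21
CX-5461 (IC50),RAD51
CX-5461 (IC50),RAD51B
CX-5461 (IC50),RAD54B
CX-5461 (IC50),RAD54L
CX-5461 (IC50),RAD9A
CX-5461 (IC50),REV1
CX-5461 (IC50),RNF168
CX-5461 (IC50),STAG2
CX-5461 (IC50),UBE2N
CX-5461 (IC50),XPA
CX-5461 (IC30),ABCF2
CX-5461 (IC30),ATM
CX-5461 (IC30),ATR
CX-5461 (IC30),BARD1
CX-5461 (IC30),CDC20
CX-5461 (IC30),CINP
CX-5461 (IC30),DNA2
CX-5461 (IC30),ERCC5
CX-5461 (IC30),H2AFX
CX-5461 (IC30),LIG4
CX-5461 (IC30),MCM9
CX-5461 (IC30),MDC1
CX-5461 (IC30),POLL
CX-5461 (IC30),POLQ
CX-5461 (IC30),RAD21
CX-5461 (IC30),RAD51
CX-5461 (IC30),RAD54L
CX-5461 (IC30),RAD9A
CX-5461 (IC30),REV1
CX-5461 (IC30),RNF168
CX-5461 (IC30),SF3B3
CX-5461 (IC30),SPO11
CX-5461 (IC30),UBE2N
CX-5461 (IC30),XPA
CX-5461 (IC30),XRCC2
PDS (IC50),APITD1
PDS (IC50),ATM
PDS (IC50),BRCC3
PDS (IC50),CDC20
PDS (IC50),CHTF18
PDS (IC50),EME1
PDS (IC50),EP300
PDS (IC50),GAPDH
PDS (IC50),GTF2H2
PDS (IC50),H2AFX
PDS (IC50),HUS1
PDS (IC50),IGF1
PDS (IC50),LIG4
PDS (IC50),MUS81
PDS (IC50),POLQ
PDS (IC50),PPP4R2
PDS (IC50),PRIM2
PDS (IC50),PSMA5
PDS (IC50),RAD51
PDS (IC50),RAD51B
PDS (IC50),RAD52
PDS (IC50),RAD54L
PDS (IC50),RAD9A
PDS (IC50),RNF168
PDS (IC50),TRRAP
PDS (IC50),UBE2C
PDS (IC30),APITD1
PDS (IC30),ATM
PDS (IC30),BARD1
PDS (IC30),BRCA2
PDS (IC30),CDC20
PDS (IC30),EP300
PDS (IC30),FANCL
PDS (IC30),H2AFX
PDS (IC30),HAUS5
PDS (IC30),INO80
PDS (IC30),INO80E
PDS (IC30),LIG4
PDS (IC30),MMS22L
PDS (IC30),MUS81
PDS (IC30),PALB2
PDS (IC30),PCNA
PDS (IC30),PNKP
PDS (IC30),POLQ
PDS (IC30),PSMB4
PDS (IC30),PSMB5
PDS (IC30),RAD21
PDS (IC30),RAD51
PDS (IC30),RAD51B
PDS (IC30),RAD52
PDS (IC30),RAD54L
PDS (IC30),RAD9A
PDS (IC30),RNF168
PDS (IC30),SMC1A
PDS (IC30),UBE2C
PDS (IC30),WEE1
PDS (IC30),XRCC2
BMH-21 (IC30),ANAPC15
BMH-21 (IC30),BCL2
BMH-21 (IC30),CDC20
BMH-21 (IC30),CEP192
BMH-21 (IC30),CHEK1
BMH-21 (IC30),IGHMBP2
BMH-21 (IC30),MCM6
BMH-21 (IC30),PMS2
BMH-21 (IC30),PNKP
BMH-21 (IC30),POLD4
BMH-21 (IC30),POLE2
BMH-21 (IC30),POLR2B
BMH-21 (IC30),POLR2L
BMH-21 (IC30),RAD23B
BMH-21 (IC30),RAD51
BMH-21 (IC30),RAD9A
BMH-21 (IC30),RDM1
BMH-21 (IC30),RFC4
BMH-21 (IC30),SUPT3H
BMH-21 (IC30),TAOK1
BMH-21 (IC30),TOPBP1
BMH-21 (IC30),UBB
BMH-21 (IC30),USP44
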