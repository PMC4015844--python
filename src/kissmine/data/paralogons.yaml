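# Reference paralogon marker sets for the four Kiss and four KissR regions.
# Symbols follow HGNC naming; total_considered is the number of genes
# tracked for region-presence assessment (it can exceed the number of
# markers listed by symbol).  The Kiss4 region carries no Kiss gene in any
# living osteichthyan and is delineated by the paralog-family members
# (TEAD1/NAV2/PPFIA1/KCNC1/PLEKHA7/PIK3C2A/SYT9) not found in the other
# three regions.
paralogons:
  Kiss1:
    markers:
      [TEAD3, NAV1, PPP1R12B, PPFIA4, MYBPH, KCNC4, REN, GOLT1A,
       PLEKHA6, PPP1R15B, PIK3C2B, SYT6]
  Kiss2:
    markers:
      [TEAD4, STRAP, PLEKHA5, GOLT1B, C12ORF39, GYS2, LDHB, KCNJ8,
       ABCC9, CMAS, SYT10]
  Kiss3:
    markers:
      [NTF4, KCNA7, PPFIA3, TEAD2, PIH1D1, ALDH16A1, KCNC3, MYBPC2, SYT3]
    total_considered: 14
  Kiss4:
    markers:
      [TEAD1, NAV2, PPFIA1, KCNC1, PLEKHA7, PIK3C2A, SYT9]
  KissR1:
    markers:
      [PALM, PTBP1, LPPR3, MED16, ARID3A, WDR18, GRIN3B, C19ORF6,
       GADD45B, DIRAS1]
  KissR2:
    markers:
      [PTPRF, KDM4A, ST3GAL3, DPH2]
  KissR3:
    markers:
      [ISCA, ZCCHC6]
  KissR4:
    markers:
      [CAMSAP3, XAB2, STXBP2, RETN, RAB3D, PALM3, NOTCH3, EPHX3, WIZ, LPAR2]
    total_considered: 11
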