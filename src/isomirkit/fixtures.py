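"""Curated example dataset from receptive-phase human endometrium.

A small bundled dataset of differentially expressed miRs/isomiRs and their
negatively correlated predicted target genes in the receptive endometrium
(hCG+7/hCG+9 versus the proliferative phase).  It serves as the package's
worked example and as a deterministic fixture: the mature-arm sequences are
published reference sequences, the variant reads are observed isomiR
sequences with their canonical names, and the regulator -> gene pairs are the
published negative-correlation table.

All sequences are RNA.  Canonical isomiR names follow the package grammar:
``{parent}_t_{o5}_{o3}`` for templated variants and
``{parent}_nont_{o5}_{o3}_{tail}`` for non-templated 3' additions.
"""

from __future__ import annotations

# Mature arms whose reference sequences are part of the example dataset.
# name -> (arm label, sequence)
FIXTURE_ARMS: dict[str, tuple[str, str]] = {
    "let-7g-5p": ("5p", "CUGUACAGGCCACUGCCUUGC"),
    "miR-10b-5p": ("5p", "UACCCUGUAGAACCGAAUUUGUG"),
    "miR-27b-3p": ("3p", "UUCACAGUGGCUAAGUUCUGC"),
    "miR-141-3p": ("3p", "UAACACUGUCUGGUAAAGAUGG"),
    "miR-199a-5p": ("5p", "CCCAGUGUUCAGACUACCUGUUC"),
    "miR-486-5p": ("5p", "UCCUGUACUGAGCUGCCCCGAG"),
}

# Observed variant reads whose parent arm is in FIXTURE_ARMS, with the
# canonical name each read must classify to.
VARIANT_READS: list[tuple[str, str]] = [
    ("miR-27b-3p_t_+1_0", "UCACAGUGGCUAAGUUCUGC"),
    ("miR-199a-5p_t_+1_0", "CCAGUGUUCAGACUACCUGUUC"),
]

# Negatively correlated (regulator, gene) pairs: each regulator is a DE
# miR/isomiR (up or down), each gene a DE transcript with the opposite sign.
# One row per (regulator, target gene).
NEGATIVE_PAIRS: list[tuple[str, str]] = [
    ("let-7g-5p", "MYCN"),
    ("let-7g-5p", "KCNC2"),
    ("let-7g-5p", "FAXC"),
    ("miR-10b-5p", "GABRB2"),
    ("miR-10a-5p_t_+1_-1", "CPED1"),
    ("miR-23a-3p_t_0_-1", "FUT9"),
    ("miR-23a-3p_t_0_-1", "ROBO2"),
    ("miR-23a-3p_t_0_-1", "CRISPLD1"),
    ("miR-23a-3p_t_0_-1", "FREM1"),
    ("miR-23a-3p_t_0_-1", "ANO4"),
    ("miR-23a-3p_t_0_-1", "FBN2"),
    ("miR-23a-3p_t_0_-1", "KCNIP4"),
    ("miR-23a-3p_t_0_-1", "GUCY1A2"),
    ("miR-23a-3p_t_0_-1", "SH3BGR"),
    ("miR-23a-3p_t_0_-1", "ZNF730"),
    ("miR-27b-3p", "EYA4"),
    ("miR-27b-3p", "SFRP1"),
    ("miR-27b-3p", "RARA"),
    ("miR-27b-3p", "BMP3"),
    ("miR-27b-3p", "CCN4"),
    ("miR-27b-3p", "SLC9A4"),
    ("miR-27b-3p", "CYP39A1"),
    ("miR-27b-3p_t_+1_0", "CYP39A1"),
    ("miR-27b-3p_t_+1_0", "LBH"),
    ("miR-27b-3p_t_+1_0", "EYA4"),
    ("miR-27b-3p_t_+1_0", "RARA"),
    ("miR-27b-3p_t_+1_0", "CCN4"),
    ("miR-30d-5p_t_0_+2", "RTKN2"),
    ("miR-30d-5p_t_0_+2", "ANO4"),
    ("miR-30d-5p_t_0_+2", "SPOCK3"),
    ("miR-30d-5p_t_0_+2", "RAPGEF4"),
    ("miR-30d-5p_t_0_+2", "GRIA2"),
    ("miR-30d-5p_t_0_+2", "OVOL1"),
    ("miR-30d-5p_t_0_+2", "PAPOLB"),
    ("miR-30d-5p_t_0_+2", "GCLC"),
    ("miR-30d-5p_t_0_+2", "CAMK4"),
    ("miR-30d-5p_t_0_+2", "NAP1L2"),
    ("miR-30d-5p_t_0_+2", "SEMA3A"),
    ("miR-30d-5p_t_+1_+2", "RTKN2"),
    ("miR-30d-5p_t_+1_+2", "ROBO2"),
    ("miR-30d-5p_t_+1_+2", "GCLC"),
    ("miR-30d-5p_t_+1_+2", "NDNF"),
    ("miR-30d-5p_t_+1_+2", "ANG"),
    ("miR-30d-5p_t_+1_+2", "SPOCK3"),
    ("miR-30d-5p_t_+1_+2", "IFIT"),
    ("miR-30d-5p_t_+1_+2", "FHOD3"),
    ("miR-30d-5p_t_+1_+2", "MYH15"),
    ("miR-30d-5p_t_+1_+2", "CSMD3"),
    ("miR-30d-5p_t_+1_+2", "FUT9"),
    ("miR-30d-5p_t_+1_+2", "ESCO2"),
    ("miR-31-5p", "LBH"),
    ("miR-92a-3p_nont_0_+2_AA", "GRHL1"),
    ("miR-92a-3p_nont_0_+2_AA", "TTC9"),
    ("miR-92a-3p_nont_0_+2_AA", "MTF1"),
    ("miR-92a-3p_nont_0_+2_AA", "IDH1"),
    ("miR-92a-3p_nont_0_+2_AA", "SOX11"),
    ("miR-92a-3p_nont_0_+2_AA", "MMP10"),
    ("miR-92a-3p_nont_0_+2_AA", "REXO1"),
    ("miR-92a-3p_nont_0_+2_AA", "IRS2"),
    ("miR-92a-3p_nont_0_+2_AA", "TWIST1"),
    ("miR-92a-3p_nont_0_+2_AA", "LRRC1"),
    ("miR-92a-3p_nont_0_+2_AA", "PIK3AP1"),
    ("miR-125a-5p_t_0_-2", "CYP24A1"),
    ("miR-125a-5p_t_0_-2", "MTF1"),
    ("miR-125a-5p_t_0_-2", "SLC7A1"),
    ("miR-125a-5p_t_0_-2", "ANKRD33B"),
    ("miR-125a-5p_t_0_-2", "PHACTR3"),
    ("miR-125a-5p_t_0_-2", "TMPRSS13"),
    ("miR-125a-5p_t_0_-2", "SOD2"),
    ("miR-125a-5p_t_0_-2", "IGSF11"),
    ("miR-125a-5p_t_+1_-2", "TRNP1"),
    ("miR-125a-5p_t_+1_-2", "DPP4"),
    ("miR-125a-5p_t_+1_-2", "STAC2"),
    ("miR-125a-5p_t_+1_-2", "CPT1A"),
    ("miR-125a-5p_t_+1_-2", "ADCY1"),
    ("miR-125a-5p_t_+1_-2", "ADAMTS8"),
    ("miR-127-3p_nont_0_+2_AU", "ATP1A2"),
    ("miR-141-3p", "ELMOD1"),
    ("miR-141-3p", "NAP1L2"),
    ("miR-141-3p", "CNTN1"),
    ("miR-141-3p", "HCN1"),
    ("miR-141-3p", "MCIDAS"),
    ("miR-141-3p", "TMEM130"),
    ("miR-148a-3p_t_0_+1", "ADGRB3"),
    ("miR-148a-3p_t_0_+1", "ROBO2"),
    ("miR-148a-3p_t_0_+1", "BMP3"),
    ("miR-148a-3p_t_0_+1", "ISM1"),
    ("miR-199a-5p", "HMCN1"),
    ("miR-199a-5p_t_+1_0", "PBK"),
    ("miR-199a-5p_t_+1_0", "EYA4"),
    ("miR-199a-5p_t_+1_0", "KCNIP4"),
    ("miR-200c-3p_t_0_-3", "PPP1R9B"),
    ("miR-200c-3p_t_0_-3", "NTRK2"),
    ("miR-200c-3p_t_0_-3", "KYNU"),
    ("miR-200c-3p_t_0_-3", "PITPNM3"),
    ("miR-200c-3p_t_0_-3", "PROK2"),
    ("miR-200c-3p_t_0_-3", "CDYL2"),
    ("miR-200c-3p_t_0_-3", "KLF6"),
    ("miR-200c-3p_t_0_-3", "SLC39A14"),
    ("miR-200c-3p_t_0_-3", "ADH1B"),
    ("miR-449c-5p_t_0_-2", "ELMOD1"),
    ("miR-449c-5p_t_0_-2", "NEXMIF"),
    ("miR-449c-5p_t_0_-2", "FUT9"),
    ("miR-449c-5p_t_+1_-1", "MYCN"),
    ("miR-449c-5p_t_+1_-1", "FUT9"),
    ("miR-449c-5p_t_+1_-1", "ELMOD1"),
    ("miR-449c-5p_t_+1_-1", "BMP3"),
    ("miR-449c-5p_t_+1_-1", "ASIC2"),
    ("miR-449c-5p_t_+1_-1", "NCEH1"),
    ("miR-449c-5p_t_+1_-1", "MCIDAS"),
    ("miR-486-5p", "FGF7"),
    ("miR-486-5p", "CEMIP"),
]
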