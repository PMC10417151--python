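"""Packaged prior-knowledge SNP panel for cisplatin ototoxicity.

Two sources: 19 variants in genes linked to cisplatin metabolism or
ototoxicity (database-derived, high functional impact or drug response),
and 7 variants previously reported as associated with cisplatin-induced
hearing loss in the systematic-review literature.  The panel enters the
feature-selection candidate pool unconditionally, alongside whatever the
inner-fold GWAS surfaces.
"""

DATABASE_PRIOR_SNPS: tuple[str, ...] = (
    "rs11572279",  # CYP2J2
    "rs9333378",   # MGST3
    "rs10498027",  # ABCA12
    "rs939336",    # ABCC5
    "rs1801206",   # WFS1
    "rs494620",    # SLC44A4
    "rs12195525",  # NOX3
    "rs17787781",  # CEP78
    "rs4917639",   # CYP2C9
    "rs2071426",   # CYP2C8
    "rs2149616",   # SYCE1
    "rs2074308",   # ABCC8
    "rs808820",    # DUSP6
    "rs2414105",   # DMXL2
    "rs10491178",  # ABCA10
    "rs3752229",   # ABCA7
    "rs2279345",   # CYP2B6
    "rs3212986",   # ERCC1
    "rs3761873",   # MCM8
)

REVIEW_PRIOR_SNPS: tuple[str, ...] = (
    "rs2075252",   # LRP2
    "rs4668123",   # LRP2
    "rs1800460",   # TPMT
    "rs4880",      # SOD2
    "rs1695",      # GSTP1
    "rs4646316",   # COMT
    "rs9332377",   # COMT
)

PRIOR_SNPS: tuple[str, ...] = DATABASE_PRIOR_SNPS + REVIEW_PRIOR_SNPS
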