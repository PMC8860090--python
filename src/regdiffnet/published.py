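"""Published summary statistics from the GSE183110 regulatory-network study.

These printed values are *inputs* used to validate the package's arithmetic:
the per-TF gene counts within the SykI- and rapamycin-favored top-10,000 edge
selections (from which nDiff, nOverlap and nRatio are recomputed through
:func:`regdiffnet.diffnet.tf_summary`), and the differential-expression
statistics of the ten ETV2 target genes used to validate candidate ranking.
The derived columns here (nDiff, nRatio) are the published cells the
recomputation is compared against, never a source for the computation.
"""

# tf, motif_id, family, nSykI, nRapa, published nDiff, published nOverlap,
# published nRatio (2 decimals)
TF_SUMMARY = [
    ("Elk4", "M0703", "ETS domain", 1106, 1064, 42, 0, 1.04),
    ("Elk3", "M0692", "ETS domain", 1051, 1005, 46, 0, 1.05),
    ("Gm5454", "M0710", "ETS domain", 1039, 972, 67, 0, 1.07),
    ("Etv3", "M0689", "ETS domain", 916, 862, 54, 0, 1.06),
    ("Erfl", "M0714", "ETS domain", 912, 869, 43, 0, 1.05),
    ("Elf4", "M0706", "ETS domain", 687, 666, 21, 0, 1.03),
    ("Etv6", "M0705", "ETS domain", 665, 618, 47, 0, 1.08),
    ("Elk1", "M6207", "ETS domain", 621, 590, 31, 0, 1.05),
    ("Id4", "M5571", "Basic helix-loop-helix", 346, 356, -10, 0, 0.97),
    ("Erf", "M5398", "ETS domain", 327, 327, 0, 0, 1.00),
    ("Myod1", "M2299", "Basic helix-loop-helix", 297, 308, -11, 0, 0.96),
    ("Tcfl3", "M0184", "Basic helix-loop-helix", 241, 242, -1, 0, 1.00),
    ("Myog", "M2300", "Basic helix-loop-helix", 200, 201, -1, 0, 1.00),
    ("Ehf", "M0696", "ETS domain", 190, 202, -12, 0, 0.94),
    ("Tcf12", "M2317", "Basic helix-loop-helix", 160, 170, -10, 0, 0.94),
    ("Gabpa", "M4568", "ETS domain", 117, 134, -17, 0, 0.87),
    ("Etv2", "M5421", "ETS domain", 116, 117, -1, 0, 0.99),
    ("Zfp740", "M0429", "C2H2-zinc finger", 98, 120, -22, 0, 0.82),
    ("Mesp1", "M5627", "Basic helix-loop-helix", 94, 111, -17, 0, 0.85),
    ("Tal1", "M6358", "Basic helix-loop-helix", 93, 110, -17, 0, 0.85),
]

# ETV2 targets in the SykI-specific network with their published
# differential-expression statistics: gene, linear fold change (sign =
# direction), p, BH q. Parpbp tops the |fold change| ranking.
ETV2_TARGET_DE = [
    ("Parpbp", -1.38, 0.00, 0.05),
    ("Fam111a", -1.22, 0.00, 0.03),
    ("Ppp1r16b", 1.22, 0.03, 0.38),
    ("Mtus1", 1.16, 0.01, 0.29),
    ("Adarb2", 1.16, 0.01, 0.25),
    ("Gldn", -1.14, 0.02, 0.35),
    ("Rnf219", -1.14, 0.03, 0.37),
    ("Il20rb", -1.13, 0.01, 0.23),
    ("Vamp1", 1.11, 0.04, 0.41),
    ("Gprc6a", -1.10, 0.03, 0.40),
]

# ETV2 consensus binding site and the promoter-construct geometry used for
# the reporter experiments: the 386-bp fragment spans -311..+75 around the
# TSS and carries one consensus site at -78; the 150-bp fragment spans
# -75..+75 and carries none. Coordinates are 1-based TSS-relative (no 0).
ETV2_CONSENSUS = "CCGGAW"
CONSTRUCT_386 = {"start": -311, "end": 75, "site_offset": -78}
CONSTRUCT_150 = {"start": -75, "end": 75, "site_offset": None}
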