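"""Published pistachio RADseq reference inputs.

Raw counts and marker sequences from the *Pistacia vera* Siirt x Bagyolu
RADseq study (18 plants: 2 parents + 8 female and 8 male F1 progeny on a
Hi-Seq 2000, 82-bp first reads).  Only *input* quantities are stored here —
read numbers, tag counts, GC and SNP tallies as printed, and the candidate
marker tag sequences; every derived column is recomputed by
:mod:`radsex.summary` and :mod:`radsex.screen`.
"""

from __future__ import annotations

import pandas as pd

#: (individual, group, read_number, n_rad_tags, gc_rate %, total_snp, het_snp_rate %)
_ROWS = [
    ("Siirt",   "female", 15_873_498, 422_422, 37.65,  90_999, 17.3),
    ("P-F-1",   "female", 24_754_856, 442_751, 37.12,  98_348, 26.9),
    ("P-F-2",   "female", 22_527_994, 513_815, 37.60,  97_562, 28.0),
    ("P-F-3",   "female", 28_035_806, 513_654, 37.07,  99_776, 25.3),
    ("P-F-4",   "female", 33_578_112, 560_479, 36.86, 101_339, 30.5),
    ("P-F-5",   "female", 23_563_272, 539_390, 37.47,  98_767, 31.9),
    ("P-F-6",   "female", 23_374_790, 523_591, 37.38,  98_876, 29.9),
    ("P-F-7",   "female", 28_326_906, 539_702, 36.88, 100_355, 27.4),
    ("P-F-8",   "female", 25_474_290, 431_895, 37.64,  96_551, 17.5),
    ("Bagyolu", "male",   27_187_532, 552_533, 38.00,  79_746, 33.1),
    ("P-M-1",   "male",   22_615_328, 498_044, 36.98,  98_046, 27.2),
    ("P-M-2",   "male",   10_108_252, 422_176, 37.10,  75_521, 20.5),
    ("P-M-3",   "male",   19_417_040, 541_272, 37.48,  95_941, 26.7),
    ("P-M-4",   "male",   11_079_312, 410_036, 38.77,  72_909, 18.6),
    ("P-M-5",   "male",   38_882_284, 657_285, 37.65, 102_340, 30.5),
    ("P-M-6",   "male",   26_158_302, 569_710, 37.58, 100_049, 27.0),
    ("P-M-7",   "male",   29_947_304, 596_268, 37.51,  99_531, 27.5),
    ("P-M-8",   "male",   39_817_004, 623_841, 37.41, 103_115, 27.8),
]

FEMALE_PARENT = "Siirt"
MALE_PARENT = "Bagyolu"


def pistachio_radseq_counts() -> pd.DataFrame:
    """Raw per-plant counts of the published 18-plant RADseq run."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "individual_id", "group", "read_number", "n_rad_tags",
            "gc_rate", "total_snp", "het_snp_rate",
        ],
    )


#: candidate sex-marker tag sequences (82 nt with the screened SNPs as
#: bracketed ambiguity letters; further unbracketed ambiguity letters are
#: additional polymorphisms on the same tag that were not assayed)
PISTACHIO_MARKER_SEQUENCES = {
    "SNP-PIS-1319":   "AATTCGTATAGCCCGTGAGAATACATG(Y)GGATGAGGGCTATACATGAGAGAGAGTACACTCACATGGCCAAGGGTT(Y)CGAAT",
    "SNP-PIS-29689":  "AATTCAACATCTTATAAAGCGAAATCACTTCA(Y)AATAATGCTTCTTCTTTGCAAGTGCACCAAACAATAT(R)TTGAATGATGA",
    "SNP-PIS-112277": "AATTCGTTA(Y)CTAGAGGGTGATTTTAAAACTCTTACAGACACAAAACCATGACAATAATT(R)AAGGAAGAAAATTCAGCATGC",
    "SNP-PIS-120693": "AATTCAATGATCTAGATT(M)AAAGAAGGCATTGGATGTTGTGTATTGTCATTTGTAA(W)AATATCTTGGTGTGTAAAATGTGTA",
    "SNP-PIS-127343": "AATTCACCAATATTTTACTGCAATAA(S)TAAGAATGTAATGACAGGGTGAGTGAAAATGGTAGATTAAAATTTTAAGGAAATG",
    "SNP-PIS-133396": "AATTCTCCTCTGTTTTTTGGGCAAACCGCAAAGAAGATTAAAGTA(S)(Y)TGATCCATGATCTTCAAGTTTCAGTACTATTCATA",
    "SNP-PIS-135862": "AATTCTTTGGTTTTGTGTCTGAATGTGGATAATATATGG(Y)(Y)GCCTCATGTTGATTATGGGAAATGTGCATGGAAATAGTATC",
    "SNP-PIS-136404": "AATTCTTTTAGGGGTTGTCAAA(K)TGACCGGATTCCTCACAAATTCAATTGCCAACTCTAAAGCTGGCAAGAAATTCTTTAGC",
    "SNP-PIS-167992": "AATTCAAACGAAAAATAACTTCATAGCGTGAGCTC(W)TTGTTCCACCTSTAACCGCAACCCTAAGCTGCAATTGATCACTTCC",
    "SNP-PIS-174431": "AATTCCATTACTTCAACAAGTCTCTAGCCGCGTACATATAAAAATTAACTACTCA(M)AGTGAAAGTGGAYAAATTGTTAAGTT",
    "SNP-PIS-176863": "AATTCCACATTTGACMAGGGTTGGAACTTTTGAGGTGGATGTGAGCTTGGAAGGTA(R)TATCATACTTTGCAGACAGGTCGAT",
}

#: the eight loci that separated the sexes with 100% accuracy in the
#: 166-plant validation panel: marker -> (position, female het pair, male
#: hom base).  Genotypes are stored on the tag (plus) strand, i.e. matching
#: the bracketed ambiguity code of the tag sequence; published rows assayed
#: by reverse-primer extension report the complement strand, and those
#: alleles have been complemented back here.
PISTACHIO_VALIDATED_LOCI = {
    "SNP-PIS-112277:61": ("SNP-PIS-112277", 61, ("A", "G"), "A"),
    "SNP-PIS-127343:27": ("SNP-PIS-127343", 27, ("C", "G"), "G"),
    "SNP-PIS-133396:46": ("SNP-PIS-133396", 46, ("C", "G"), "G"),
    "SNP-PIS-133396:47": ("SNP-PIS-133396", 47, ("C", "T"), "C"),
    "SNP-PIS-135862:41": ("SNP-PIS-135862", 41, ("C", "T"), "T"),
    "SNP-PIS-136404:23": ("SNP-PIS-136404", 23, ("G", "T"), "G"),
    "SNP-PIS-167992:36": ("SNP-PIS-167992", 36, ("A", "T"), "A"),
    "SNP-PIS-174431:56": ("SNP-PIS-174431", 56, ("A", "C"), "C"),
}
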