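"""Published reference data for the *FTO* intron 1 obesity-risk SNP cluster.

Fifteen GWAS SNPs (hg19, chromosome 16) with their risk / low-risk allele
orientation, the published per-locus among-supergroup AMOVA percent-variation
profile, and the published frequency tables of the six major 15-letter
haplotypes and their 10-letter cores across the four continental supergroups
(AFR, EAS, EUR, SAS).  These constants drive the default simulation scenario
and serve as desk-check anchors.

Coordinates marked approximate were not part of the published per-SNP
coordinate list; they are plausible in-cluster placements that preserve the
panel order and are used only to emit well-formed VCF.
"""

from __future__ import annotations

from .panel import SnpPanel, SnpRecord

# rsid, pos(hg19), risk, other(low-risk), CpG-change flag, GWAS p-value
_PANEL_ROWS = [
    ("rs6499640",  53_769_677, "A", "G", False, 4e-13),
    ("rs9940128",  53_800_753, "A", "G", True,  4e-23),
    ("rs1421085",  53_800_953, "C", "T", False, 6e-39),
    ("rs1558902",  53_803_574, "A", "T", False, 2e-223),
    ("rs1121980",  53_809_246, "A", "G", False, 4e-8),
    ("rs62033400", 53_811_787, "G", "A", False, 2e-14),
    ("rs17817449", 53_813_367, "G", "T", True,  2e-12),
    ("rs8043757",  53_813_450, "T", "A", False, 5e-110),
    ("rs8050136",  53_816_274, "A", "C", False, 2e-58),
    ("rs11075990", 53_817_856, "G", "A", True,  2e-51),
    ("rs9939609",  53_820_527, "A", "T", False, 4e-51),
    ("rs7202116",  53_821_614, "G", "A", True,  2e-10),
    ("rs7185735",  53_822_651, "G", "A", False, 1e-79),
    ("rs17817964", 53_828_065, "T", "C", False, 1e-10),
    ("rs12149832", 53_842_908, "A", "G", True,  5e-22),
]


def fto_panel() -> SnpPanel:
    """The 15-SNP risk-oriented *FTO* intron 1 panel."""
    return SnpPanel(
        SnpRecord(
            rsid=rsid, chrom="16", pos=pos, risk_allele=risk, other_allele=other,
            cpg_flag=cpg, panel_index=i, gwas_pvalue=p,
        )
        for i, (rsid, pos, risk, other, cpg, p) in enumerate(_PANEL_ROWS, start=1)
    )


#: supergroup labels in the published table column order
SUPERGROUPS = ("SAS", "AFR", "EAS", "EUR")

#: published per-locus AMOVA among-supergroup percent variation (loci 1..15)
PER_LOCUS_PERCENT_AMONG_GROUPS = (
    16.56, 4.81, 14.42, 14.53, 5.80, 13.09, 5.69, 6.30, 7.09,
    9.28, 9.28, 9.31, 9.31, 12.45, 13.66,
)

#: published per-locus SSD and Va (among-group variance component), loci 1..15
PER_LOCUS_SSD = (
    116.99, 31.31, 73.86, 74.28, 37.86, 65.43, 33.74, 37.79, 42.97,
    57.99, 57.99, 58.13, 58.13, 62.22, 70.26,
)
PER_LOCUS_VA = (
    0.04, 0.01, 0.03, 0.03, 0.01, 0.02, 0.01, 0.01, 0.02,
    0.02, 0.02, 0.02, 0.02, 0.02, 0.03,
)

#: percent-variation threshold below which positions are dropped
POSITION_FILTER_THRESHOLD = 8.0

#: panel positions dropped by the variance filter (1-based panel_index)
DROPPED_POSITIONS = frozenset({2, 5, 7, 8, 9})

#: the six major 15-letter haplotypes and their supergroup frequencies
FULL_HAPLOTYPE_FREQS: dict[str, dict[str, float]] = {
    "GGTTGATACATAACG": {"SAS": 0.277, "AFR": 0.183, "EAS": 0.598, "EUR": 0.271},
    "AGTTGATACATAACG": {"SAS": 0.256, "AFR": 0.240, "EAS": 0.129, "EUR": 0.199},
    "AACAAGGTAGAGGTA": {"SAS": 0.118, "AFR": 0.004, "EAS": 0.054, "EUR": 0.295},
    "GACAAGGTAGAGGTA": {"SAS": 0.120, "AFR": 0.036, "EAS": 0.079, "EUR": 0.054},
    "AATTAAGTAGAGGCG": {"SAS": 0.000, "AFR": 0.240, "EAS": 0.000, "EUR": 0.000},
    "GATTAATACATAACG": {"SAS": 0.067, "AFR": 0.006, "EAS": 0.041, "EUR": 0.000},
}

#: the published 10-letter core haplotype frequencies (after dropping 2,5,7-9)
CORE_HAPLOTYPE_FREQS: dict[str, dict[str, float]] = {
    "GTTAATAACG": {"SAS": 0.344, "AFR": 0.195, "EAS": 0.643, "EUR": 0.271},
    "ATTAATAACG": {"SAS": 0.267, "AFR": 0.303, "EAS": 0.130, "EUR": 0.208},
    "ACAGGAGGTA": {"SAS": 0.118, "AFR": 0.00358, "EAS": 0.0537, "EUR": 0.297},
    "ATTAGAGGCG": {"SAS": 0.0, "AFR": 0.35, "EAS": 0.0, "EUR": 0.0},
    "GCAGGAGGTA": {"SAS": 0.120, "AFR": 0.0358, "EAS": 0.0785, "EUR": 0.0543},
    "GTTAGAGGCG": {"SAS": 0.0, "AFR": 0.101, "EAS": 0.00199, "EUR": 0.0},
}

#: published Yin-Yang (fully complementary) core haplotype pair
YIN_YANG_CORES = ("GTTAATAACG", "ACAGGAGGTA")

#: panel positions highly monomorphic in the ancestral (AFR) supergroup
AFR_MONOMORPHIC_POSITIONS = frozenset({3, 4, 6, 14, 15})

#: default population layout: 18 populations in 4 supergroups, 2000 individuals
DEFAULT_POPULATIONS: dict[str, dict[str, int]] = {
    "AFR": {"ESN": 99, "GWD": 113, "LWK": 99, "MSL": 85, "YRI": 108},   # 504
    "EAS": {"CDX": 93, "CHB": 103, "CHS": 105, "JPT": 104, "KHV": 99},  # 504
    "EUR": {"CEU": 126, "GBR": 126, "IBS": 126, "TSI": 125},            # 503
    "SAS": {"BEB": 123, "GIH": 122, "ITU": 122, "PJL": 122},            # 489
}
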