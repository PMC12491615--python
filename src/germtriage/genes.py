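"""Default curated gene sets.

The DDR/PCa universe covers DNA-damage-repair genes and genes with
reported prostate-cancer germline variants; the known germline-testing
(GT) panel is the subset already carried by clinical PCa panels.  CHIP
genes carry their literature prevalence rank; CHIP-suspect genes extend
the conservative missing-VAF exclusion policy.  All sets are replaceable
via TSV inputs (:func:`germtriage.variant_io.read_gene_lists`).
"""
from __future__ import annotations

from .types import GeneLists

KNOWN_GT_GENES = frozenset(
    {
        "BRCA1", "BRCA2", "ATM", "CHEK2", "TP53", "RAD50", "RAD54L", "NBN",
        "PMS2", "MSH6", "FANCA", "PALB2", "BARD1", "HOXB13", "CDK12",
        "MLH1", "MSH2", "BRIP1",
    }
)

DDR_PCA_GENES = KNOWN_GT_GENES | frozenset(
    {
        "RECQL4", "FANCD2", "TRRAP", "CHD1L", "ASPM", "LRP1B", "ERBB4",
        "MSH3", "ROS1", "EGFR", "PREX2", "MYC", "JAK2", "APTX", "FANCG",
        "RET", "CHD4", "ERBB3", "POLE", "BUB1B", "INO80", "BLM", "NF1",
        "JAK3", "DONSON", "U2AF1", "STAG2", "POLG", "POLQ", "CREBBP",
        "FAT1", "HERC2", "PMS1", "TET2", "DNMT3A", "PPM1D", "ERCC2",
        "ERCC4", "ERCC6", "CLSPN", "KMT2A", "KMT2C", "KMT2D", "RTEL1",
        "FANCE", "FANCI", "MRE11", "MUTYH", "RAD23B", "NDRG1", "LEF1",
        "PER1", "PRDM2", "FGFR4",
    }
)

#: CHIP-associated genes with literature prevalence rank
CHIP_GENES = {"DNMT3A": 1, "TET2": 2, "PPM1D": 4, "TP53": 5, "JAK2": 7}

#: genes under the conservative missing-VAF exclusion policy
CHIP_SUSPECT_GENES = frozenset({"TRRAP", "KMT2C"})

#: decoy symbols outside the candidate universe (exercise the gene-set filter)
DECOY_GENES = (
    "TTN", "MUC16", "OBSCN", "AHNAK2", "FLG", "PCLO", "CSMD1", "RYR2",
    "LRP2", "OR2T4",
)


def default_gene_lists() -> GeneLists:
    return GeneLists(
        ddr_pca_genes=DDR_PCA_GENES,
        known_gt_genes=KNOWN_GT_GENES,
        chip_genes=dict(CHIP_GENES),
        chip_suspect_genes=CHIP_SUSPECT_GENES,
    )
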