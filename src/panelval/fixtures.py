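"""Built-in validation fixtures for the 1021-gene panel workflow.

These encode the published analytical/clinical validation inputs of the
assay as structured data, so the validation arithmetic can be recomputed
from scratch: reference-control confusion counts across VAF/depth tiers,
the MSI and HER2 orthogonal-comparison counts, the ten paired
tissue/plasma case call sets, the cohort tallies behind the clinical
summary fractions, and reference-standard variant lists for simulation.

Genomic loci attached to the paired-case variants are synthetic
placeholders (variant identity in the source report is carried by gene +
HGVS label, which has no public coordinates); they are assigned once and
used consistently in both compartments so identity matching behaves as it
would on real coordinates.
"""

from __future__ import annotations

from .biomarkers import Tier, ActionabilityRecord
from .calls import (
    Compartment,
    ConfusionCounts,
    TruthVariant,
    VariantCall,
    VariantKind,
)

__all__ = [
    "reference_control_rows",
    "msi_validation_counts",
    "her2_fish_counts",
    "paired_validation_cases",
    "cohort_counts",
    "cohort_actionability_records",
    "cohort_hrr_calls",
    "ovarian_gloh_flags",
    "s800_truth_variants",
    "lod_tier_truth",
]


def reference_control_rows() -> list[dict]:
    """Reference-control confusion counts per standard / variant type / tier.

    The two custom standards (2% and 0.5% VAF) carry 27 SNV/indels, 3 CNVs
    and 6 fusions each, all detected.  The 1-1.3%-VAF standard has a
    40-variant tier universe: 39 detected at 993x mean depth, 37 at 560x.
    The 0.5-0.65% equimolar wild-type mix yielded 34/40 at 794x.
    """
    return [
        {"name": "S800-1", "type": "SNV/INDEL", "tp": 27, "fp": 0, "fn": 0, "depth": 1000, "vaf": 0.02},
        {"name": "S800-1", "type": "CNV", "tp": 3, "fp": 0, "fn": 0, "depth": 1000, "vaf": 0.02},
        {"name": "S800-1", "type": "FUSION", "tp": 6, "fp": 0, "fn": 0, "depth": 1000, "vaf": 0.02},
        {"name": "S800-2", "type": "SNV/INDEL", "tp": 27, "fp": 0, "fn": 0, "depth": 2000, "vaf": 0.005},
        {"name": "S800-2", "type": "CNV", "tp": 3, "fp": 0, "fn": 0, "depth": 2000, "vaf": 0.005},
        {"name": "S800-2", "type": "FUSION", "tp": 6, "fp": 0, "fn": 0, "depth": 2000, "vaf": 0.005},
        {"name": "Tru-Q7-993x", "type": "SNV/INDEL", "tp": 39, "fp": 0, "fn": 1, "depth": 993, "vaf": 0.013},
        {"name": "Tru-Q7-560x", "type": "SNV/INDEL", "tp": 37, "fp": 0, "fn": 3, "depth": 560, "vaf": 0.013},
        {"name": "Tru-Q7+Q0-794x", "type": "SNV/INDEL", "tp": 34, "fp": 0, "fn": 6, "depth": 794, "vaf": 0.006},
    ]


def msi_validation_counts() -> ConfusionCounts:
    """MSI orthogonal comparison: 66 samples, 17 MSI-high all detected,
    48 of 49 stable samples classified stable."""
    return ConfusionCounts(tp=17, fp=1, fn=0, tn=48)


def her2_fish_counts() -> ConfusionCounts:
    """HER2 amplification vs FISH: 10/12 FISH-positive called positive,
    10/10 FISH-negative called negative."""
    return ConfusionCounts(tp=10, fp=0, fn=2, tn=10)


_SMALL = VariantKind.SNV
_LOCI: dict[str, tuple[str, int, str, str]] = {}


def _small(
    compartment: Compartment, gene: str, hgvs: str, vaf_pct: float, indel: bool = False
) -> VariantCall:
    """A small-variant call at a stable synthetic locus keyed by gene+HGVS."""
    key = f"{gene}:{hgvs}"
    if key not in _LOCI:
        idx = len(_LOCI) + 1
        ref, alt = ("CAT", "C") if indel else ("A", "G")
        _LOCI[key] = (f"chr{1 + idx % 22}", 1_000_000 + 1000 * idx, ref, alt)
    chrom, pos, ref, alt = _LOCI[key]
    return VariantCall(
        kind=VariantKind.INDEL if indel else _SMALL,
        compartment=compartment,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        vaf=vaf_pct / 100.0,
        annotations={"hgvs": hgvs},
    )


def _cnv(compartment: Compartment, gene: str, copies: float) -> VariantCall:
    return VariantCall(kind=VariantKind.CNV, compartment=compartment, gene=gene, copies=copies)


def _fusion(compartment: Compartment, g5: str, g3: str, vaf: float, **ann) -> VariantCall:
    return VariantCall(
        kind=VariantKind.FUSION, compartment=compartment, gene=g5, gene2=g3,
        vaf=vaf, annotations=ann,
    )


def paired_validation_cases() -> list[tuple[list[VariantCall], list[VariantCall]]]:
    """The ten paired tissue/plasma validation cases as (tissue, plasma)
    call-set tuples.  Three cases (4, 5 and 8) had no tissue alteration
    recovered in plasma — no detectable circulating tumor DNA."""
    T, P = Compartment.FFPE, Compartment.PLASMA
    cases: list[tuple[list[VariantCall], list[VariantCall]]] = []

    # case 1: four small variants + four co-amplified 11q13 genes
    cases.append((
        [
            _small(T, "ERRFI1", "c.1007_1016del", 46.0, indel=True),
            _small(T, "TERT", "-146T>C", 35.0),
            _small(T, "PALB2", "c.1A>G", 21.0),
            _small(T, "TP53", "c.743G>T", 49.0),
            _cnv(T, "CCND1", 10.0),
            _cnv(T, "FGF19", 10.0),
            _cnv(T, "FGF4", 10.0),
            _cnv(T, "FGF3", 10.0),
        ],
        [
            _small(P, "ERRFI1", "c.1007_1016del", 0.50, indel=True),
            _small(P, "TERT", "-146T>C", 0.90),
            _small(P, "PALB2", "c.1A>G", 0.80),
            _small(P, "TP53", "c.743G>T", 1.60),
            _cnv(P, "CCND1", 3.2),
            _cnv(P, "FGF19", 3.2),
            _cnv(P, "FGF4", 3.2),
            _cnv(P, "FGF3", 3.2),
        ],
    ))
    # case 2
    cases.append((
        [
            _small(T, "PIK3CA", "c.328_330del", 7.0, indel=True),
            _small(T, "CDH1", "c.67C>T", 10.0),
        ],
        [
            _small(P, "PIK3CA", "c.328_330del", 4.90, indel=True),
            _small(P, "CDH1", "c.67C>T", 8.50),
        ],
    ))
    # case 3
    cases.append((
        [_small(T, "EGFR", "c.2573T>G", 34.0), _small(T, "TP53", "c.413C>T", 46.0)],
        [_small(P, "EGFR", "c.2573T>G", 32.40), _small(P, "TP53", "c.413C>T", 6.50)],
    ))
    # case 4: nothing detected in plasma
    cases.append((
        [
            _small(T, "KRAS", "c.38G>A", 42.0),
            _small(T, "BAP1", "c.783+2T>C", 22.0),
            _small(T, "CDKN2A", "c.151-1G>T", 29.0),
        ],
        [],
    ))
    # case 5: nothing detected in plasma
    cases.append((
        [
            _small(T, "NRAS", "c.183A>C", 15.0),
            _small(T, "APC", "c.4280delC", 60.0, indel=True),
            _small(T, "ERBB3", "c.695C>T", 16.0),
            _small(T, "KDM5A", "c.641T>A", 13.20),
        ],
        [],
    ))
    # case 6
    cases.append((
        [
            _small(T, "KRAS", "c.35G>A", 28.60),
            _small(T, "RET", "c.2410G>A", 32.44),
            _small(T, "IDH1", "c.395G>T", 20.52),
            _small(T, "TP53", "c.614A>G", 40.66),
        ],
        [
            _small(P, "KRAS", "c.35G>A", 3.00),
            _small(P, "RET", "c.2410G>A", 1.42),
            _small(P, "IDH1", "c.395G>T", 0.98),
            _small(P, "TP53", "c.614A>G", 2.24),
        ],
    ))
    # case 7: fusion recovered in plasma
    cases.append((
        [_fusion(T, "EML4", "ALK", 0.50, supporting_reads=2416, breakpoints="EML4(6)-ALK(20)")],
        [_fusion(P, "EML4", "ALK", 0.012, breakpoints="EML4(6)-ALK(20)")],
    ))
    # case 8: nothing detected in plasma
    cases.append((
        [
            _small(T, "CTNNB1", "c.121A>G", 42.20),
            _fusion(T, "CD74", "ROS1", 0.50, supporting_reads=3895),
        ],
        [],
    ))
    # case 9
    cases.append((
        [_small(T, "TP53", "c.814G>T", 44.30)],
        [_small(P, "TP53", "c.814G>T", 0.55)],
    ))
    # case 10
    cases.append((
        [
            _small(T, "KRAS", "c.35G>T", 32.25),
            _small(T, "PIK3CA", "c.3139C>T", 12.69),
            _small(T, "MAP2K7", "c.289C>T", 13.47),
            _small(T, "TP53", "c.734G>A", 11.70),
        ],
        [
            _small(P, "KRAS", "c.35G>T", 0.68),
            _small(P, "PIK3CA", "c.3139C>T", 1.72),
            _small(P, "MAP2K7", "c.289C>T", 0.30),
            _small(P, "TP53", "c.734G>A", 0.60),
        ],
    ))
    return cases


def cohort_counts() -> dict:
    """Clinical-cohort tallies behind the summary fractions.

    1368 samples attempted, 1345 successfully profiled; 10,805 alterations
    of which 7,160 oncogenic/likely oncogenic; most-actionable tier counts
    over the 1345 profiled patients; immunotherapy-marker counts; HRR
    loss-of-function counts; the 70-patient ovarian gLOH subgroup.
    """
    return {
        "n_attempted": 1368,
        "n_success": 1345,
        "n_alterations": 10805,
        "n_oncogenic": 7160,
        "on_label": 169,
        "off_label": 591,
        "resistance": 80,
        "none": 505,
        "msi_high": 16,
        "tmb_high": 124,
        "combined_on_label": 271,
        "hrr_any": 296,
        "hrr_brca": 50,
        "hrr_high_risk": 72,
        "ovarian_n": 70,
        "ovarian_high_gloh": 36,
        "ovarian_parp_eligible": 40,
    }


def cohort_actionability_records() -> list[ActionabilityRecord]:
    """Per-patient actionability records consistent with the cohort tallies.

    Tier counts follow :func:`cohort_counts`; immunotherapy flags are
    allocated so that 124 patients are TMB-high and 16 MSI-high (disjoint
    sets), of whom 38 already carry an on-label variant — the combined
    (targeted + immunotherapy) on-label roll-up therefore covers 271
    patients.  The allocation to individual synthetic patients is
    arbitrary; every cohort fraction depends only on the tallies.
    """
    c = cohort_counts()
    tiers = (
        [Tier.ON_LABEL] * c["on_label"]
        + [Tier.OFF_LABEL] * c["off_label"]
        + [Tier.RESISTANCE] * c["resistance"]
        + [Tier.NONE] * c["none"]
    )
    assert len(tiers) == c["n_success"]
    flags_on_label = 38  # flag carriers already on-label
    records = []
    n_tmb = n_msi = 0
    for i, tier in enumerate(tiers):
        tmb_high = msi_high = False
        if tier is Tier.ON_LABEL and i < flags_on_label:
            tmb_high = True
        elif tier is not Tier.ON_LABEL:
            # flags continue past the on-label block until quotas are met
            if n_tmb < c["tmb_high"] - flags_on_label:
                tmb_high = True
                n_tmb += 1
            elif n_msi < c["msi_high"]:
                msi_high = True
                n_msi += 1
        records.append(
            ActionabilityRecord(
                patient=f"C{i:04d}", tiers=[tier], msi_high=msi_high, tmb_high=tmb_high
            )
        )
    return records


def cohort_hrr_calls() -> dict[str, list[VariantCall]]:
    """Per-patient HRR call sets consistent with the cohort tallies:
    50 patients with BRCA1/2 loss of function, 22 with PALB2/RAD51C, and
    224 with other HRR genes (ATM most prevalent), 296 in total of 1345."""
    c = cohort_counts()
    calls: dict[str, list[VariantCall]] = {}

    def lof(gene: str) -> VariantCall:
        return VariantCall(
            kind=VariantKind.SNV, compartment=Compartment.FFPE, chrom="chr1",
            pos=500_000, ref="A", alt="T", gene=gene, vaf=0.3,
            annotations={"lof": True},
        )

    i = 0
    for gene, count in (
        ("BRCA1", 25), ("BRCA2", 25), ("PALB2", 12), ("RAD51C", 10),
        ("ATM", 90), ("CHEK2", 50), ("FANCA", 40), ("BAP1", 24), ("FANCM", 20),
    ):
        for _ in range(count):
            calls[f"H{i:04d}"] = [lof(gene)]
            i += 1
    assert i == c["hrr_any"]
    while i < c["n_success"]:
        calls[f"H{i:04d}"] = []
        i += 1
    return calls


def ovarian_gloh_flags() -> list[dict]:
    """The 70-patient ovarian subgroup: 36 with elevated genome LOH and 4
    additional patients eligible for PARP inhibitors through high-risk HRR
    alterations only (40 eligible in total)."""
    c = cohort_counts()
    flags = []
    for i in range(c["ovarian_n"]):
        high_gloh = i < c["ovarian_high_gloh"]
        hrr_high_risk = c["ovarian_high_gloh"] <= i < c["ovarian_parp_eligible"]
        flags.append({"patient": f"OV{i:03d}", "high_gloh": high_gloh,
                      "hrr_high_risk": hrr_high_risk})
    return flags


def s800_truth_variants(design_vaf: float, design_copies: float = 6.0) -> list[TruthVariant]:
    """Truth list shaped like the custom reference standards: 27 SNV/indels
    in clinically relevant genes, 3 amplifications, 6 fusions, all at one
    design VAF."""
    genes = ["EGFR", "KRAS", "NRAS", "KIT", "BRAF", "PIK3CA", "TP53", "MET", "ERBB2"]
    variants: list[TruthVariant] = []
    for i in range(27):
        variants.append(
            TruthVariant(
                kind=VariantKind.INDEL if i % 9 == 8 else VariantKind.SNV,
                chrom=f"chr{1 + i % 7}",
                pos=10_000_000 + 50_000 * i,
                ref="ACT" if i % 9 == 8 else "C",
                alt="A" if i % 9 == 8 else "T",
                gene=genes[i % len(genes)],
                design_vaf=design_vaf,
            )
        )
    for gene in ("ERBB2", "MET", "MYCN"):
        variants.append(TruthVariant(kind=VariantKind.CNV, gene=gene, design_copies=design_copies))
    for g5, g3 in (("EML4", "ALK"), ("CD74", "ROS1"), ("KIF5B", "RET"),
                   ("CCDC6", "RET"), ("SLC34A2", "ROS1"), ("STRN", "ALK")):
        variants.append(
            TruthVariant(kind=VariantKind.FUSION, gene=g5, gene2=g3, design_vaf=design_vaf)
        )
    return variants


def lod_tier_truth(design_vaf: float, n_variants: int = 40) -> list[TruthVariant]:
    """A limit-of-detection tier: ``n_variants`` SNVs at one design VAF."""
    return [
        TruthVariant(
            kind=VariantKind.SNV,
            chrom=f"chr{1 + i % 22}",
            pos=5_000_000 + 25_000 * i,
            ref="G",
            alt="A",
            gene=f"GENE{i:02d}",
            design_vaf=design_vaf,
        )
        for i in range(n_variants)
    ]
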