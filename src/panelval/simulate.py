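"""Synthetic inputs for the validation pipeline.

No public call-level dataset accompanies a clinical panel validation, so
every downstream stage here runs on simulated inputs whose statistical
structure matches the study designs being emulated:

* reference standards — fixed variant lists at design VAFs (0.5-2%),
  sequenced to a target depth; per-variant read support is binomial in the
  sampled depth, and a variant is called when its alternate-read count and
  observed VAF clear the caller's reporting floor;
* clinical cohorts — per-patient gene alterations by independent Bernoulli
  draws, log-normal TMB, Bernoulli MSI-high status, and a genome-LOH value
  for designated tumor types, with actionability tiers attached from a
  gene -> tier table;
* paired tissue/plasma samples — plasma VAFs are tissue VAFs diluted by
  the circulating-tumor-DNA fraction (zero when the tumor does not shed);
* SNP BAF/logR profiles under the allele-specific copy-number model of
  :mod:`panelval.loh`, with Gaussian noise and random allele phase;
* microsatellite site tables with an exact unstable fraction.

All randomness descends from one integer seed through
``numpy.random.SeedSequence`` children, so identical specs reproduce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarkers import Tier
from .calls import Compartment, TruthSet, TruthVariant, VariantCall, VariantKind
from .loh import SnpProfile, expected_baf, expected_logr

__all__ = [
    "ReferenceStandardSpec",
    "CohortSpec",
    "PairedSampleSpec",
    "SegmentSpec",
    "simulate_reference_standard",
    "simulate_cohort",
    "simulate_paired_tissue_plasma",
    "simulate_snp_profile",
    "simulate_msi_sites",
    "CNV_NOISE_SD",
]

#: Gaussian sd of observed copy number around truth, per compartment.
CNV_NOISE_SD = {Compartment.FFPE: 0.15, Compartment.PLASMA: 0.30}


@dataclass
class ReferenceStandardSpec:
    """A reference standard: known variants at design VAFs plus sequencing
    conditions.  ``reporting_min_vaf`` is the caller's observed-VAF floor
    (0 = detection governed purely by ``min_alt_reads``); compartment
    positivity filtering is a separate downstream stage."""

    name: str
    variants: Sequence[TruthVariant]
    depth_target: int
    n_replicates: int = 1
    seed: int = 0
    compartment: Compartment = Compartment.FFPE
    min_alt_reads: int = 3
    reporting_min_vaf: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_target <= 0:
            raise ValueError("depth_target must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        keys = [v.identity_key() for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("variant loci must be unique per standard")
        for v in self.variants:
            vaf = v.design_vaf
            if VariantKind(v.kind) is VariantKind.CNV:
                continue
            if vaf is None or not (0.0 <= vaf <= 1.0):
                raise ValueError(f"design VAF must be in [0, 1]: {v}")


def simulate_reference_standard(
    spec: ReferenceStandardSpec,
) -> tuple[list[list[VariantCall]], TruthSet]:
    """Simulate replicate sequencing runs of a reference standard.

    Per replicate and SNV/indel truth variant: depth ~ Poisson(target),
    alternate reads ~ Binomial(depth, design VAF); a call is emitted iff
    alt reads >= ``min_alt_reads`` and observed VAF >= ``reporting_min_vaf``.
    Fusions follow the same support model.  CNVs always yield an observed
    copy number = design copies + Gaussian noise (compartment-specific sd);
    thresholding is left to positivity filtering.
    """
    truth = TruthSet(name=spec.name, variants=list(spec.variants))
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    replicates: list[list[VariantCall]] = []
    for child in children:
        rng = np.random.default_rng(child)
        calls: list[VariantCall] = []
        for v in spec.variants:
            kind = VariantKind(v.kind)
            if kind is VariantKind.CNV:
                noise = rng.normal(0.0, CNV_NOISE_SD[spec.compartment])
                calls.append(
                    VariantCall(
                        kind=kind,
                        compartment=spec.compartment,
                        gene=v.gene,
                        copies=max(float(v.design_copies) + noise, 0.0),
                    )
                )
                continue
            depth = int(rng.poisson(spec.depth_target))
            alt = int(rng.binomial(depth, v.design_vaf)) if depth > 0 else 0
            if depth <= 0 or alt < spec.min_alt_reads:
                continue
            vaf = alt / depth
            if vaf < spec.reporting_min_vaf:
                continue
            calls.append(
                VariantCall(
                    kind=kind,
                    compartment=spec.compartment,
                    chrom=v.chrom,
                    pos=v.pos,
                    ref=v.ref,
                    alt=v.alt,
                    gene=v.gene,
                    gene2=v.gene2,
                    vaf=vaf,
                    depth=depth,
                )
            )
        replicates.append(calls)
    return replicates, truth


@dataclass
class CohortSpec:
    """Generative description of a clinical cohort.

    Gene alterations are independent Bernoulli draws; TMB is log-normal
    (``tmb_log_mean``/``tmb_log_sd`` on the natural-log scale of muts/Mb);
    MSI-high is Bernoulli; tumor types in ``gloh_tumor_types`` receive a
    genome-LOH percentage ~ Normal(``gloh_mean``, ``gloh_sd``) clipped to
    [0, 100].  ``actionability`` maps gene -> Tier for attached annotations.
    """

    n_patients: int
    tumor_type_mix: dict
    gene_alteration_freqs: dict = field(default_factory=dict)
    msi_high_prob: float = 0.0119
    tmb_log_mean: float = 1.2
    tmb_log_sd: float = 0.9
    gloh_tumor_types: tuple = ("ovarian",)
    gloh_mean: float = 15.0
    gloh_sd: float = 8.0
    actionability: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.tumor_type_mix:
            raise ValueError("empty tumor type mix")
        total = sum(self.tumor_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tumor type proportions must sum to 1, got {total}")
        for gene, p in self.gene_alteration_freqs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"alteration frequency for {gene} outside [0, 1]")
        if not (0.0 <= self.msi_high_prob <= 1.0):
            raise ValueError("msi_high_prob outside [0, 1]")


def simulate_cohort(spec: CohortSpec) -> list[dict]:
    """Draw a cohort of patients with alterations and biomarker values.

    Returns one dict per patient: ``patient``, ``tumor_type``, ``calls``
    (tier-annotated :class:`VariantCall` SNVs, one per altered gene),
    ``tmb`` (muts/Mb), ``msi_high``, ``msi_score`` and ``gloh`` (percent,
    or None outside the designated tumor types).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    types = list(spec.tumor_type_mix)
    probs = np.array([spec.tumor_type_mix[t] for t in types])
    probs = probs / probs.sum()
    genes = sorted(spec.gene_alteration_freqs)
    gene_p = np.array([spec.gene_alteration_freqs[g] for g in genes])

    patients: list[dict] = []
    for i in range(spec.n_patients):
        ttype = types[int(rng.choice(len(types), p=probs))]
        altered = (
            [g for g, hit in zip(genes, rng.random(len(genes)) < gene_p) if hit]
            if genes
            else []
        )
        calls = [
            VariantCall(
                kind=VariantKind.SNV,
                compartment=Compartment.FFPE,
                chrom="chr1",
                pos=1000 + k,
                ref="A",
                alt="T",
                gene=g,
                vaf=float(np.clip(rng.beta(2, 4), 0.01, 1.0)),
                annotations={
                    "tier": spec.actionability.get(g, Tier.NONE),
                    "lof": True,
                },
            )
            for k, g in enumerate(altered)
        ]
        msi_high = bool(rng.random() < spec.msi_high_prob)
        msi_score = (
            float(rng.uniform(0.25, 0.6)) if msi_high else float(rng.uniform(0.0, 0.12))
        )
        tmb = float(rng.lognormal(spec.tmb_log_mean, spec.tmb_log_sd))
        gloh = (
            float(np.clip(rng.normal(spec.gloh_mean, spec.gloh_sd), 0.0, 100.0))
            if ttype in spec.gloh_tumor_types
            else None
        )
        patients.append(
            {
                "patient": f"P{i:05d}",
                "tumor_type": ttype,
                "calls": calls,
                "tmb": tmb,
                "msi_high": msi_high,
                "msi_score": msi_score,
                "gloh": gloh,
            }
        )
    return patients


@dataclass
class PairedSampleSpec:
    """One patient's tumor truth and the plasma dilution conditions.

    Plasma design VAF = tissue VAF x ``ctdna_fraction`` (never above the
    tissue VAF); ``shedding=False`` models a tumor releasing no DNA into
    plasma, forcing every plasma design VAF to zero.
    """

    tissue_variants: Sequence[TruthVariant]
    ctdna_fraction: float
    plasma_depth: int
    tissue_depth: int = 1000
    shedding: bool = True
    min_alt_reads: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ctdna_fraction <= 1.0):
            raise ValueError("ctdna_fraction must be in [0, 1]")
        if self.plasma_depth <= 0 or self.tissue_depth <= 0:
            raise ValueError("depths must be > 0")


def simulate_paired_tissue_plasma(
    spec: PairedSampleSpec,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Simulate one patient's tissue and plasma call sets.

    Both compartments use the binomial detection model of
    :func:`simulate_reference_standard`; plasma design VAFs are the tissue
    VAFs scaled by the ctDNA fraction (copy numbers are diluted toward the
    diploid baseline 2).  A non-shedding tumor yields an empty plasma
    tumor signal.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(2)

    def _dilute(v: TruthVariant) -> TruthVariant | None:
        frac = spec.ctdna_fraction if spec.shedding else 0.0
        if VariantKind(v.kind) is VariantKind.CNV:
            copies = 2.0 + (float(v.design_copies) - 2.0) * frac
            return TruthVariant(kind=v.kind, gene=v.gene, design_copies=copies)
        vaf = (v.design_vaf or 0.0) * frac
        if vaf == 0.0:
            return None
        return TruthVariant(
            kind=v.kind, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            gene=v.gene, gene2=v.gene2, design_vaf=vaf,
        )

    tissue_spec = ReferenceStandardSpec(
        name="tissue",
        variants=list(spec.tissue_variants),
        depth_target=spec.tissue_depth,
        seed=int(seeds[0].generate_state(1)[0] % (2**31)),
        compartment=Compartment.FFPE,
        min_alt_reads=spec.min_alt_reads,
    )
    plasma_variants = [d for v in spec.tissue_variants if (d := _dilute(v)) is not None]
    tissue_calls = simulate_reference_standard(tissue_spec)[0][0]
    if not plasma_variants:
        return tissue_calls, []
    plasma_spec = ReferenceStandardSpec(
        name="plasma",
        variants=plasma_variants,
        depth_target=spec.plasma_depth,
        seed=int(seeds[1].generate_state(1)[0] % (2**31)),
        compartment=Compartment.PLASMA,
        min_alt_reads=spec.min_alt_reads,
    )
    plasma_calls = simulate_reference_standard(plasma_spec)[0][0]
    return tissue_calls, plasma_calls


@dataclass(frozen=True)
class SegmentSpec:
    """Ground-truth allele-specific state of one genomic stretch."""

    chrom: str
    length_bp: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("segment length must be > 0")
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValueError("require n_major >= n_minor >= 0")


def simulate_snp_profile(
    purity: float,
    segments: Sequence[SegmentSpec],
    ploidy: float | None = None,
    snps_per_mb: float = 50.0,
    baf_sd: float = 0.02,
    logr_sd: float = 0.05,
    seed: int = 0,
) -> SnpProfile:
    """SNP BAF/logR observations under the allele-specific CN model.

    Segments are laid end-to-end per chromosome; SNP positions are uniform
    within each segment; each SNP's BAF is the model expectation with a
    random allele phase (b or 1-b) plus Gaussian noise, clipped to [0, 1];
    logR gets Gaussian noise.  ``ploidy=None`` uses the length-weighted
    mean total copy number of the truth segments.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if not segments:
        raise ValueError("zero-length profile")
    if ploidy is None:
        w = np.array([s.length_bp for s in segments], dtype=float)
        tot = np.array([s.n_major + s.n_minor for s in segments], dtype=float)
        ploidy = float(np.average(tot, weights=w))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    offsets: dict = {}
    rows = []
    for seg in segments:
        start = offsets.get(seg.chrom, 0)
        n_snps = max(int(round(seg.length_bp / 1e6 * snps_per_mb)), 2)
        if seg.length_bp > 4 * n_snps:
            pos = np.sort(
                np.unique((rng.random(n_snps) * (seg.length_bp - 1)).astype(np.int64) + 1)
            )
        else:
            pos = np.arange(1, min(n_snps, seg.length_bp) + 1)
        n_snps = len(pos)
        b = float(expected_baf(purity, seg.n_major, seg.n_minor))
        r = float(expected_logr(purity, ploidy, seg.n_major, seg.n_minor))
        phase = rng.random(n_snps) < 0.5
        baf = np.where(phase, b, 1.0 - b) + rng.normal(0.0, baf_sd, n_snps)
        logr = r + rng.normal(0.0, logr_sd, n_snps)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": seg.chrom,
                    "pos": start + pos,
                    "baf": np.clip(baf, 0.0, 1.0),
                    "logr": logr,
                }
            )
        )
        offsets[seg.chrom] = start + seg.length_bp
    data = pd.concat(rows, ignore_index=True)
    # de-duplicate positions that collide across adjacent segments
    data = data.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return SnpProfile(data=data, chrom_lengths=dict(offsets))


def simulate_msi_sites(
    n_sites: int, unstable_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Microsatellite site table with an exact unstable-site count.

    Exactly ``round(n_sites * unstable_fraction)`` sites are unstable; the
    assignment to site ids is shuffled by the seed.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if not (0.0 <= unstable_fraction <= 1.0):
        raise ValueError("unstable_fraction must be in [0, 1]")
    n_unstable = int(round(n_sites * unstable_fraction))
    unstable = np.zeros(n_sites, dtype=bool)
    unstable[:n_unstable] = True
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rng.shuffle(unstable)
    return pd.DataFrame(
        {"site": [f"MS{i:04d}" for i in range(n_sites)], "unstable": unstable}
    )
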