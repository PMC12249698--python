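"""Variant data model, positivity filtering, and identity matching.

A comprehensive genomic profiling assay reports four alteration classes —
SNVs, small indels, copy-number variants (CNVs) and gene fusions — from two
specimen compartments: FFPE tumor tissue and plasma cell-free DNA.  This
module defines the canonical :class:`VariantCall` record, the compartment
specific positivity thresholds (:class:`PositivityPolicy`), and the identity
rules used to match called variants against truth sets
(:func:`match_calls`) and across paired tissue/plasma samples
(:func:`pair_concordance`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "VariantKind",
    "Compartment",
    "VariantCall",
    "TruthVariant",
    "TruthSet",
    "PositivityPolicy",
    "ConfusionCounts",
    "apply_positivity",
    "match_calls",
    "pair_concordance",
    "normalize_indel",
]


class VariantKind(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    CNV = "CNV"
    FUSION = "FUSION"


class Compartment(str, enum.Enum):
    FFPE = "FFPE"
    PLASMA = "PLASMA"


def normalize_indel(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize an indel to a minimal left-aligned representation.

    Trims the shared suffix, then the shared prefix (keeping one anchor base
    when either allele would become empty), so that equivalent VCF spellings
    of the same event compare equal.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VariantCall:
    """One called alteration with compartment-specific quantitation.

    Exactly the fields relevant to ``kind`` are meaningful: SNV/indel carry
    (chrom, pos, ref, alt, vaf); CNV carries (gene, copies); fusion carries
    the ordered gene pair, optional breakpoints and a support fraction in
    ``vaf``.  ``annotations`` holds pass-through labels (consequence class,
    HGVS, loss-of-function flag, actionability tier, distance to splice).
    """

    kind: VariantKind
    compartment: Compartment
    chrom: str | None = None
    pos: int | None = None  # 1-based (VCF convention)
    ref: str | None = None
    alt: str | None = None
    gene: str | None = None
    gene2: str | None = None  # fusion 3' partner
    breakpoints: tuple[int, int] | None = None
    vaf: float | None = None
    copies: float | None = None
    depth: int | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = VariantKind(self.kind)
        self.compartment = Compartment(self.compartment)
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.copies is not None and self.copies < 0:
            raise ValueError(f"copies must be >= 0, got {self.copies}")

    def identity_key(self) -> tuple:
        """Hashable identity used for truth matching and pairing.

        SNV/indel: (chrom, normalized pos/ref/alt).  CNV: gene symbol.
        Fusion: unordered gene pair (breakpoints carried but not required).
        """
        if self.kind in (VariantKind.SNV, VariantKind.INDEL):
            if self.chrom is None or self.pos is None:
                raise ValueError(f"SNV/indel call missing locus: {self}")
            pos, ref, alt = normalize_indel(self.pos, self.ref or "", self.alt or "")
            return ("small", self.chrom, pos, ref, alt)
        if self.kind is VariantKind.CNV:
            if not self.gene:
                raise ValueError(f"CNV call missing gene symbol: {self}")
            return ("cnv", self.gene)
        if not self.gene or not self.gene2:
            raise ValueError(f"fusion call missing gene pair: {self}")
        return ("fusion", frozenset((self.gene, self.gene2)))


@dataclass(frozen=True)
class TruthVariant:
    """Expected variant of a reference standard, with its design VAF."""

    kind: VariantKind
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    gene: str | None = None
    gene2: str | None = None
    design_vaf: float | None = None  # fraction; None for CNV
    design_copies: float | None = None

    def identity_key(self) -> tuple:
        kind = VariantKind(self.kind)
        if kind in (VariantKind.SNV, VariantKind.INDEL):
            pos, ref, alt = normalize_indel(self.pos, self.ref or "", self.alt or "")
            return ("small", self.chrom, pos, ref, alt)
        if kind is VariantKind.CNV:
            return ("cnv", self.gene)
        return ("fusion", frozenset((self.gene, self.gene2)))


@dataclass
class TruthSet:
    """Expected variants of a reference standard or simulated tumor.

    ``negative_positions`` is the declared wild-type universe used for
    specificity/NPA; without it, true-negative counts are undefined.
    """

    name: str
    variants: list[TruthVariant]
    negative_positions: list[tuple] | None = None

    def __post_init__(self) -> None:
        keys = [v.identity_key() for v in self.variants]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate truth entries in {self.name}: {sorted(map(str, dupes))}")


@dataclass
class PositivityPolicy:
    """Compartment-specific reporting thresholds.

    SNV/indel/fusion calls are positive at VAF >= the compartment threshold
    (inclusive); CNVs at copy number >= 3.0 in tissue and >= 2.2 in plasma;
    MSI-high at unstable-site fraction >= 19.5% (FFPE) / 18% (plasma).
    The default plasma small-variant threshold is 0.5%, the lowest VAF tier
    the assay validates; :meth:`per_label` gives the literal 1%-everywhere
    labelled rule.
    """

    snv_indel_min_vaf_ffpe: float = 0.01
    snv_indel_min_vaf_plasma: float = 0.005
    cnv_min_copies_ffpe: float = 3.0
    cnv_min_copies_plasma: float = 2.2
    msi_cutoff_ffpe: float = 0.195
    msi_cutoff_plasma: float = 0.18

    def __post_init__(self) -> None:
        for name in (
            "snv_indel_min_vaf_ffpe",
            "snv_indel_min_vaf_plasma",
            "cnv_min_copies_ffpe",
            "cnv_min_copies_plasma",
            "msi_cutoff_ffpe",
            "msi_cutoff_plasma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cnv_min_copies_plasma >= self.cnv_min_copies_ffpe:
            raise ValueError("plasma CNV cutoff must be below the tissue cutoff")

    @classmethod
    def per_label(cls) -> "PositivityPolicy":
        """The labelled rule: >=1% VAF in both compartments."""
        return cls(snv_indel_min_vaf_plasma=0.01)

    def min_vaf(self, compartment: Compartment) -> float:
        if Compartment(compartment) is Compartment.FFPE:
            return self.snv_indel_min_vaf_ffpe
        return self.snv_indel_min_vaf_plasma

    def min_copies(self, compartment: Compartment) -> float:
        if Compartment(compartment) is Compartment.FFPE:
            return self.cnv_min_copies_ffpe
        return self.cnv_min_copies_plasma

    def msi_cutoff(self, compartment: Compartment) -> float:
        if Compartment(compartment) is Compartment.FFPE:
            return self.msi_cutoff_ffpe
        return self.msi_cutoff_plasma


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies; ``tn`` is None when no negative universe exists."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be >= 0")

    @property
    def tn_defined(self) -> bool:
        return self.tn is not None


def apply_positivity(
    calls: Iterable[VariantCall], policy: PositivityPolicy | None = None
) -> list[VariantCall]:
    """Filter calls to those meeting the compartment positivity thresholds.

    SNV/indel/fusion are retained iff VAF >= threshold (inclusive); CNVs iff
    copy number >= the compartment cutoff.  Order is preserved and the
    filter is idempotent.  A call missing its quantitation raises.
    """
    policy = policy or PositivityPolicy()
    kept: list[VariantCall] = []
    for call in calls:
        if call.kind is VariantKind.CNV:
            if call.copies is None:
                raise ValueError(f"CNV call missing copy number: {call.gene}")
            if call.copies >= policy.min_copies(call.compartment):
                kept.append(call)
        else:
            if call.vaf is None:
                raise ValueError(f"call missing VAF: {call.identity_key()}")
            if call.vaf >= policy.min_vaf(call.compartment):
                kept.append(call)
    return kept


def match_calls(
    calls: Sequence[VariantCall], truth: TruthSet
) -> tuple[ConfusionCounts, list[dict]]:
    """Match calls against a truth set.

    SNV/indel match on normalized (chrom, pos, ref, alt); CNVs on gene
    symbol; fusions on the unordered gene pair.  Each truth variant matches
    at most one call.  Returns confusion counts and a per-variant table of
    dicts (truth key, matched call or None, status).  True negatives are
    counted over the truth set's declared negative positions when present;
    otherwise ``tn`` is None (undefined), never silently zero.
    """
    if not truth.variants:
        raise ValueError("truth set is empty")
    truth_by_key = {t.identity_key(): t for t in truth.variants}
    matched: dict[tuple, VariantCall] = {}
    fp_calls: list[VariantCall] = []
    for call in calls:
        key = call.identity_key()
        if key in truth_by_key and key not in matched:
            matched[key] = call
        else:
            fp_calls.append(call)

    table: list[dict] = []
    for t in truth.variants:
        key = t.identity_key()
        call = matched.get(key)
        table.append(
            {
                "key": key,
                "truth": t,
                "call": call,
                "status": "TP" if call is not None else "FN",
            }
        )
    for call in fp_calls:
        table.append({"key": call.identity_key(), "truth": None, "call": call, "status": "FP"})

    tn: int | None = None
    if truth.negative_positions is not None:
        fp_keys = {c.identity_key() for c in fp_calls}
        neg = [tuple(p) for p in truth.negative_positions]
        tn = sum(1 for p in neg if p not in fp_keys)
    counts = ConfusionCounts(
        tp=len(matched), fp=len(fp_calls), fn=len(truth.variants) - len(matched), tn=tn
    )
    return counts, table


def pair_concordance(
    tissue_calls: Sequence[VariantCall], plasma_calls: Sequence[VariantCall]
) -> tuple[list[dict], bool]:
    """Compare one patient's tissue and plasma call sets variant-by-variant.

    Variants are matched under the same identity rules as truth matching.
    The case is concordant iff at least one tissue variant is recovered in
    plasma (a patient whose plasma shows none of the tissue alterations has
    no detectable circulating tumor DNA).  The table reports, per tissue
    variant, tissue VAF/copies against plasma VAF/copies, with plasma fields
    None ("Not Detected") where absent; plasma-only variants are appended.
    """
    plasma_by_key: dict[tuple, VariantCall] = {}
    for call in plasma_calls:
        plasma_by_key.setdefault(call.identity_key(), call)

    table: list[dict] = []
    n_found = 0
    seen = set()
    for t_call in tissue_calls:
        key = t_call.identity_key()
        seen.add(key)
        p_call = plasma_by_key.get(key)
        if p_call is not None:
            n_found += 1
        table.append(
            {
                "key": key,
                "tissue_vaf": t_call.vaf,
                "tissue_copies": t_call.copies,
                "plasma_vaf": p_call.vaf if p_call else None,
                "plasma_copies": p_call.copies if p_call else None,
                "detected_in_plasma": p_call is not None,
            }
        )
    for key, p_call in plasma_by_key.items():
        if key not in seen:
            table.append(
                {
                    "key": key,
                    "tissue_vaf": None,
                    "tissue_copies": None,
                    "plasma_vaf": p_call.vaf,
                    "plasma_copies": p_call.copies,
                    "detected_in_plasma": True,
                }
            )
    case_concordant = n_found >= 1
    return table, case_concordant
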